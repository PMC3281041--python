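"""Readers and writers for the pipeline's plain-text formats.

FASTA/FASTQ go through Biopython; tabular intermediates are TSV via pandas so
every number in a report can be audited from the emitted files. Raw libraries
round-trip either as tag-count TSV (columns: tag, count — adaptor-only
artifacts as an empty tag field) or as FASTQ with one record per copy.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cleaning import CleanTagTable, RawTagLibrary
from .virtual_tags import most_3prime_tag


def write_fasta(genes: Mapping[str, str], path) -> None:
    """Reference transcripts; the description flags 3'-tag capability."""
    records = [
        SeqRecord(
            Seq(seq),
            id=gene_id,
            description=f"taggable={'yes' if most_3prime_tag(seq) else 'no'}",
        )
        for gene_id, seq in genes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_raw_tsv(raw: RawTagLibrary, path) -> None:
    rows = [{"tag": t, "count": c} for t, c in sorted(raw.tags.items())]
    if raw.adaptor_only:
        rows.append({"tag": "", "count": raw.adaptor_only})
    pd.DataFrame(rows, columns=["tag", "count"]).to_csv(path, sep="\t", index=False)


def read_raw_tsv(path, library_id: str = "") -> RawTagLibrary:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tag": str, "count": int})
    raw = RawTagLibrary(library_id or Path(path).stem)
    for tag, count in zip(df["tag"], df["count"]):
        if tag == "":
            raw.adaptor_only += int(count)
        else:
            raw.tags[tag] = raw.tags.get(tag, 0) + int(count)
    return raw


def write_raw_fastq(raw: RawTagLibrary, path, quality: str = "I") -> None:
    """Expand the multiset to one FASTQ record per copy (fixed quality).

    Adaptor-only artifacts carry no tag sequence and are not representable as
    reads; they survive only in the TSV form.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    i = 0
    with opener(path, "wt") as fh:
        for tag, count in sorted(raw.tags.items()):
            for _ in range(count):
                i += 1
                fh.write(f"@tag{i}\n{tag}\n+\n{quality * len(tag)}\n")


def read_raw_fastq(path, library_id: str = "") -> RawTagLibrary:
    path = str(path)
    raw = RawTagLibrary(library_id or Path(path).split("/")[-1])
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
    with handle:
        for rec in SeqIO.parse(handle, "fastq"):
            tag = str(rec.seq).upper()
            raw.tags[tag] = raw.tags.get(tag, 0) + 1
    return raw


def write_clean_tsv(table: CleanTagTable, path) -> None:
    pd.DataFrame(
        [{"tag": t, "count": c} for t, c in sorted(table.counts.items())],
        columns=["tag", "count"],
    ).to_csv(path, sep="\t", index=False)


def read_clean_tsv(path, library_id: str = "") -> CleanTagTable:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return CleanTagTable(
        library_id or Path(path).stem, dict(zip(df["tag"], df["count"]))
    )


def read_annotation_tsv(path) -> pd.DataFrame:
    """Two-column (gene, term) table; term ids are opaque labels."""
    return pd.read_csv(path, sep="\t", dtype=str)
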