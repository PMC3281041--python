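"""End-to-end orchestration: simulate/load -> clean -> index -> map -> TPM ->
pairwise differential expression -> enrichment -> reports.

Every intermediate is written as TSV under the run directory so each number in
the rendered reports can be recomputed from the emitted files; a manifest lists
every output. Runs are seed-deterministic: identical config gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import io as tio
from .cleaning import CleanTagTable, LibraryStats, clean_raw_tags
from .differential import call_de_genes, summarize_de
from .enrichment import AnnotationSet, enrich_all_terms
from .expression import compute_tpm
from .mapping import MappingResult, map_library
from .reporting import cleaning_report, de_report, library_report
from .simulate import SimConfig, simulate_experiment
from .virtual_tags import build_index, extract_virtual_tags, index_to_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run.

    Either ``simulate`` is set (self-contained synthetic run) or ``reference``
    plus ``raw_libraries`` point at existing files.
    """

    out_dir: Path
    simulate: Optional[SimConfig] = None
    reference: Optional[Path] = None
    genome: Optional[Path] = None
    raw_libraries: Dict[str, Path] = field(default_factory=dict)
    annotation: Optional[Path] = None
    fdr: float = 0.001
    lfc: float = 1.0
    sig_mode: str = "fdr"
    correction: str = "bh"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulate is None and (self.reference is None or not self.raw_libraries):
            raise ValueError("need either a simulator block or reference + raw libraries")
        if not (0 < self.fdr < 1) or self.lfc < 0 or not (0 < self.alpha < 1):
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("simulate", None)
        cfg = cls(
            out_dir=Path(data.pop("out_dir", "tagdge_run")),
            simulate=SimConfig(**sim) if sim else None,
            reference=Path(data["reference"]) if data.get("reference") else None,
            genome=Path(data["genome"]) if data.get("genome") else None,
            raw_libraries={k: Path(v) for k, v in data.pop("raw_libraries", {}).items()},
            annotation=Path(data["annotation"]) if data.get("annotation") else None,
            **{k: v for k, v in data.items()
               if k in ("fdr", "lfc", "sig_mode", "correction", "alpha", "seed")},
        )
        return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    stats: Dict[str, LibraryStats]
    mappings: Dict[str, MappingResult]
    de_tables: Dict[str, pd.DataFrame]
    de_summaries: pd.DataFrame
    enrichment: Dict[str, pd.DataFrame]
    manifest: List[str]


def _genome_kmers_from_fasta(path) -> set:
    from .virtual_tags import TAG_LENGTH

    kmers = set()
    for seq in tio.read_fasta(path).values():
        for i in range(len(seq) - TAG_LENGTH + 1):
            window = seq[i : i + TAG_LENGTH]
            if window.startswith("CATG") and "N" not in window:
                kmers.add(window)
    return kmers


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage, write all TSVs and reports, return in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: List[str] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        manifest.append(name)

    stage = "input"
    try:
        if config.simulate is not None:
            stage = "simulate"
            genes, raw_libraries, truth = simulate_experiment(config.simulate)
            tio.write_fasta(genes, out / "reference.fasta")
            manifest.append("reference.fasta")
            truth.expression.rename_axis("gene").to_csv(out / "truth_expression.tsv", sep="\t")
            truth.de_labels.rename_axis("gene").to_csv(out / "truth_de_labels.tsv", sep="\t")
            manifest += ["truth_expression.tsv", "truth_de_labels.tsv"]
            for lib, prov in truth.provenance.items():
                emit(prov, f"truth_provenance_{lib}.tsv")
            for lib, raw in raw_libraries.items():
                tio.write_raw_tsv(raw, out / f"raw_{lib}.tsv")
                manifest.append(f"raw_{lib}.tsv")
            (out / "config.yaml").write_text(
                yaml.safe_dump(dataclasses.asdict(config.simulate))
            )
            manifest.append("config.yaml")
            genome_kmers = None
        else:
            genes = tio.read_fasta(config.reference)
            raw_libraries = {
                lib: (tio.read_raw_fastq(path, lib) if str(path).endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz"))
                      else tio.read_raw_tsv(path, lib))
                for lib, path in config.raw_libraries.items()
            }
            genome_kmers = _genome_kmers_from_fasta(config.genome) if config.genome else None

        stage = "clean"
        cleans: Dict[str, CleanTagTable] = {}
        stats: Dict[str, LibraryStats] = {}
        for lib, raw in raw_libraries.items():
            table, st = clean_raw_tags(raw)
            cleans[lib], stats[lib] = table, st
            tio.write_clean_tsv(table, out / f"clean_{lib}.tsv")
            manifest.append(f"clean_{lib}.tsv")
            emit(cleaning_report(st), f"cleaning_report_{lib}.tsv")
            logger.info(
                "library %s: raw=%d clean=%d (adaptor=%d, N=%d, singleton=%d, malformed=%d)",
                lib, st.raw_total, st.clean_total, st.adaptor_only_copies,
                st.n_copies, st.singleton_copies, st.malformed_copies,
            )

        stage = "index"
        index = build_index(genes, genome_kmers)
        emit(index_to_table(index), "virtual_tag_index.tsv")

        stage = "map"
        mappings: Dict[str, MappingResult] = {}
        for lib, table in cleans.items():
            mapping = map_library(table, index)
            mappings[lib] = mapping
            emit(mapping.per_gene_table(), f"gene_counts_{lib}.tsv")
            emit(library_report(stats[lib], mapping, len(genes)), f"library_stats_{lib}.tsv")

        stage = "tpm"
        universe = sorted(genes)
        expr = {
            lib: compute_tpm(mappings[lib].gene_counts, cleans[lib].clean_total,
                             lib, gene_universe=universe)
            for lib in cleans
        }
        for lib, table in expr.items():
            emit(table.to_frame().reset_index(), f"expression_{lib}.tsv")

        stage = "de"
        lib_ids = list(cleans)
        de_tables: Dict[str, pd.DataFrame] = {}
        summaries = []
        de_gene_sets: Dict[str, set] = {}
        for i in range(len(lib_ids)):
            for j in range(i + 1, len(lib_ids)):
                a, b = lib_ids[i], lib_ids[j]
                name = f"{a}_vs_{b}"
                calls = call_de_genes(
                    expr[a], expr[b], fdr=config.fdr, lfc=config.lfc,
                    sig_mode=config.sig_mode,
                )
                de_tables[name] = calls
                emit(calls, f"de_{name}.tsv")
                summaries.append(summarize_de(calls, name))
                de_gene_sets[name] = set(calls.loc[calls["call"] != "ns", "gene"])
        de_summary_frame = de_report(summaries)
        emit(de_summary_frame, "de_summary.tsv")

        stage = "enrichment"
        enrichment_tables: Dict[str, pd.DataFrame] = {}
        if config.annotation is not None:
            annotation = AnnotationSet.from_table(tio.read_annotation_tsv(config.annotation))
            for name, de_set in de_gene_sets.items():
                table = enrich_all_terms(
                    annotation, de_set, correction=config.correction, alpha=config.alpha
                )
                enrichment_tables[name] = table
                emit(table, f"enrichment_{name}.tsv")
    except Exception as exc:  # noqa: BLE001 - annotate stage, then re-raise
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(sorted(manifest), indent=2) + "\n")
    return PipelineResult(
        out_dir=out,
        stats=stats,
        mappings=mappings,
        de_tables=de_tables,
        de_summaries=de_summary_frame,
        enrichment=enrichment_tables,
        manifest=sorted(manifest),
    )
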