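"""Virtual tag reference for NlaIII/MmeI digital gene expression.

In the DGE protocol, NlaIII cuts transcripts at CATG sites and MmeI releases a
21-nt tag: the CATG anchor plus the following 17 nt. The *virtual tag library*
enumerates every such tag derivable from every reference transcript, so that
observed sequencing tags can be assigned to genes. A tag owned by more than one
gene is *ambiguous* and can never yield an unambiguous gene assignment.

Lookups tolerate at most one substitution, and only within the 17-nt variable
region: the CATG anchor is defined by the restriction chemistry, so a read whose
anchor is corrupted would never have been recognized as a tag in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

ANCHOR = "CATG"
TAG_LENGTH = 21
VARIABLE_LENGTH = TAG_LENGTH - len(ANCHOR)  # 17
_BASES = "ACGT"


@dataclass(frozen=True)
class VirtualTag:
    """A 21-nt CATG-anchored tag together with its gene ownership.

    ``site_rank`` counts CATG sites from the 3' end of the owning transcript
    (1 = 3'-most). When the same sequence occurs in several genes the merged
    index entry keeps the smallest rank seen.
    """

    sequence: str
    gene_ids: FrozenSet[str]
    site_rank: int

    @property
    def ambiguous(self) -> bool:
        return len(self.gene_ids) > 1

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(self.sequence)}")
        if not self.sequence.startswith(ANCHOR):
            raise ValueError(f"tag must start with {ANCHOR}: {self.sequence!r}")
        if not self.gene_ids:
            raise ValueError("tag must have at least one owning gene")


def extract_virtual_tags(gene_id: str, sequence: str) -> List[VirtualTag]:
    """Enumerate all CATG+17-nt tags of one transcript, 3' to 5'.

    Every CATG occurrence with at least 17 nt downstream yields one tag; sites
    closer to the 3' end than that are skipped (the MmeI cut would run off the
    fragment). Windows containing N are skipped. An empty sequence yields an
    empty list.
    """
    sequence = sequence.upper()
    positions: List[int] = []
    start = sequence.find(ANCHOR)
    while start != -1:
        if start + TAG_LENGTH <= len(sequence):
            positions.append(start)
        start = sequence.find(ANCHOR, start + 1)
    tags: List[VirtualTag] = []
    rank = 0
    for pos in reversed(positions):  # 3'-most first
        window = sequence[pos : pos + TAG_LENGTH]
        if "N" in window:
            continue
        rank += 1
        tags.append(VirtualTag(window, frozenset({gene_id}), rank))
    return tags


def most_3prime_tag(sequence: str) -> Optional[str]:
    """The tag the sequencing protocol would emit for this transcript, or None.

    Bead precipitation retains the 3'-most restriction fragment, so a physical
    library samples only the 3'-most valid CATG site of each transcript.
    """
    tags = extract_virtual_tags("_", sequence)
    return tags[0].sequence if tags else None


def variable_region_neighbors(tag: str) -> Iterable[str]:
    """The 51 tags at Hamming distance 1 within the 17-nt variable region."""
    for i in range(len(ANCHOR), TAG_LENGTH):
        for base in _BASES:
            if base != tag[i]:
                yield tag[:i] + base + tag[i + 1 :]


def hamming_variable(a: str, b: str) -> int:
    """Hamming distance over the 17-nt variable region of two 21-nt tags."""
    return sum(x != y for x, y in zip(a[len(ANCHOR) :], b[len(ANCHOR) :]))


@dataclass
class VirtualTagIndex:
    """Exact-sequence map of virtual tags, plus an optional genome 21-mer set.

    ``lookup`` prefers exact matches; only if no exact entry exists does it fall
    back to the 51-variant 1-mismatch neighborhood. The genome k-mer set serves
    as a secondary reference for tags that hit no gene.
    """

    tags: Dict[str, VirtualTag] = field(default_factory=dict)
    genome_kmers: Optional[FrozenSet[str]] = None

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.tags

    def lookup(self, sequence: str) -> Tuple[List[VirtualTag], Optional[int]]:
        """Best-distance gene lookup: ([hits], distance) with distance 0 or 1.

        Returns ``([], None)`` when nothing matches within one mismatch.
        """
        hit = self.tags.get(sequence)
        if hit is not None:
            return [hit], 0
        hits = []
        seen: Set[str] = set()
        for neighbor in variable_region_neighbors(sequence):
            vt = self.tags.get(neighbor)
            if vt is not None and vt.sequence not in seen:
                seen.add(vt.sequence)
                hits.append(vt)
        if hits:
            return hits, 1
        return [], None

    def genome_lookup(self, sequence: str) -> Optional[int]:
        """Distance (0 or 1) to the genome 21-mer set, or None if no hit."""
        if not self.genome_kmers:
            return None
        if sequence in self.genome_kmers:
            return 0
        for neighbor in variable_region_neighbors(sequence):
            if neighbor in self.genome_kmers:
                return 1
        return None


def build_index(
    genes: Mapping[str, str],
    genome_kmers: Optional[Iterable[str]] = None,
) -> VirtualTagIndex:
    """Build the virtual tag index over all CATG sites of all reference genes.

    All sites are enumerated per transcript (not only the 3'-most): internal
    sites catch tags from incomplete digestion and are what "all possible tags"
    must mean for a reference. Sequences shared across genes are merged into one
    entry with every owner recorded.
    """
    if not genes:
        raise ValueError("need at least one reference gene")
    merged: Dict[str, Tuple[Set[str], int]] = {}
    for gene_id, sequence in genes.items():
        for vt in extract_virtual_tags(gene_id, sequence):
            if vt.sequence in merged:
                owners, rank = merged[vt.sequence]
                owners.update(vt.gene_ids)
                merged[vt.sequence] = (owners, min(rank, vt.site_rank))
            else:
                merged[vt.sequence] = (set(vt.gene_ids), vt.site_rank)
    tags = {
        seq: VirtualTag(seq, frozenset(owners), rank)
        for seq, (owners, rank) in merged.items()
    }
    kmers = frozenset(genome_kmers) if genome_kmers is not None else None
    return VirtualTagIndex(tags=tags, genome_kmers=kmers)


def index_to_table(index: VirtualTagIndex):
    """Inspection table: tag, comma-joined gene ids, site_rank, ambiguous."""
    import pandas as pd

    rows = [
        {
            "tag": vt.sequence,
            "gene_ids": ",".join(sorted(vt.gene_ids)),
            "site_rank": vt.site_rank,
            "ambiguous": vt.ambiguous,
        }
        for vt in sorted(index.tags.values(), key=lambda t: t.sequence)
    ]
    return pd.DataFrame(rows, columns=["tag", "gene_ids", "site_rank", "ambiguous"])
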