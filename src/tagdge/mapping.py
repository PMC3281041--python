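"""Mapping clean tags to the virtual tag reference.

Each clean tag is assigned, at its best distance (exact preferred over one
mismatch), to one of four categories:

* ``gene_unambiguous`` — the best-distance hit set names exactly one gene;
* ``gene_all`` — gene hits exist but span more than one gene (the category
  ``gene_all`` in totals additionally *includes* the unambiguous tags: it is
  "all tags mapping to genes", of which the unambiguous ones are a subset);
* ``genome`` — no gene hit, but the tag is within one mismatch of the genome
  21-mer set;
* ``unknown`` — nothing within one mismatch anywhere.

Precedence is gene > genome > unknown; ambiguity is judged only within the best
distance stratum, so an exact unique hit is never discarded because a 1-mismatch
neighbor exists elsewhere. Hits to several sites of the same gene count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Set, Tuple

import pandas as pd

from .cleaning import CleanTagTable
from .virtual_tags import VirtualTagIndex

CATEGORIES = ("gene_unambiguous", "gene_all", "genome", "unknown")


def map_tag(
    tag: str, index: VirtualTagIndex
) -> Tuple[str, FrozenSet[str], Optional[int]]:
    """Classify one 21-nt tag: (category, owning gene ids, mismatches).

    ``gene_ids`` is empty for genome/unknown tags; ``mismatches`` is None for
    unknown tags.
    """
    hits, distance = index.lookup(tag)
    if hits:
        genes: Set[str] = set()
        for vt in hits:
            genes.update(vt.gene_ids)
        category = "gene_unambiguous" if len(genes) == 1 else "gene_all"
        return category, frozenset(genes), distance
    genome_distance = index.genome_lookup(tag)
    if genome_distance is not None:
        return "genome", frozenset(), genome_distance
    return "unknown", frozenset(), None


@dataclass
class MappingResult:
    """Aggregate mapping of one clean library.

    ``copies``/``distinct`` hold per-category totals; ``gene_all`` is the
    all-gene-mapped total (superset of ``gene_unambiguous``), and the partition
    gene_all + genome + unknown equals the clean total on both bases.
    ``gene_counts`` are the per-gene unambiguous copy counts used for
    expression; ``gene_distinct`` the distinct unambiguous tags per gene.
    """

    library_id: str
    clean_total: int
    distinct_clean: int
    copies: Dict[str, int] = field(default_factory=dict)
    distinct: Dict[str, int] = field(default_factory=dict)
    gene_counts: Dict[str, int] = field(default_factory=dict)
    gene_distinct: Dict[str, int] = field(default_factory=dict)
    genes_all: Set[str] = field(default_factory=set)
    tag_category: Dict[str, str] = field(default_factory=dict)

    @property
    def genes_unambiguous(self) -> Set[str]:
        return set(self.gene_counts)

    def count_table(self) -> Dict[str, int]:
        """Flat count table consumable by :func:`tagdge.cleaning.summarize_library`."""
        out = {
            "clean_total": self.clean_total,
            "distinct_clean": self.distinct_clean,
            "genes_all": len(self.genes_all),
            "genes_unambiguous": len(self.gene_counts),
        }
        for cat in CATEGORIES:
            out[cat] = self.copies.get(cat, 0)
            out[f"distinct_{cat}"] = self.distinct.get(cat, 0)
        return out

    def per_gene_table(self) -> pd.DataFrame:
        genes = sorted(self.gene_counts)
        return pd.DataFrame(
            {
                "gene": genes,
                "unambiguous_copies": [self.gene_counts[g] for g in genes],
                "distinct_tags": [self.gene_distinct.get(g, 0) for g in genes],
            }
        )


def map_library(
    clean: CleanTagTable,
    index: VirtualTagIndex,
    genome_mode: str = "remainder",
) -> MappingResult:
    """Map every clean tag, weighted by copy number, into category totals.

    ``genome_mode`` controls what the genome category counts: ``"remainder"``
    (default) tests only tags that hit no gene, so the categories partition the
    library; ``"all"`` additionally reports gene-mapped tags that also hit the
    genome k-mer set (overlapping totals, partition kept via the remainder for
    unknown).
    """
    if genome_mode not in ("remainder", "all"):
        raise ValueError(f"unknown genome_mode: {genome_mode!r}")
    if len(index) == 0:
        raise ValueError("virtual tag index is empty")
    result = MappingResult(
        library_id=clean.library_id,
        clean_total=clean.clean_total,
        distinct_clean=clean.distinct_clean,
    )
    copies = {cat: 0 for cat in CATEGORIES}
    distinct = {cat: 0 for cat in CATEGORIES}
    genome_overlap_copies = 0
    genome_overlap_distinct = 0
    for tag, count in clean.counts.items():
        category, genes, _ = map_tag(tag, index)
        result.tag_category[tag] = category
        if category in ("gene_unambiguous", "gene_all"):
            copies["gene_all"] += count
            distinct["gene_all"] += 1
            result.genes_all.update(genes)
            if category == "gene_unambiguous":
                (g,) = genes
                copies["gene_unambiguous"] += count
                distinct["gene_unambiguous"] += 1
                result.gene_counts[g] = result.gene_counts.get(g, 0) + count
                result.gene_distinct[g] = result.gene_distinct.get(g, 0) + 1
            if genome_mode == "all" and index.genome_lookup(tag) is not None:
                genome_overlap_copies += count
                genome_overlap_distinct += 1
        elif category == "genome":
            copies["genome"] += count
            distinct["genome"] += 1
        else:
            copies["unknown"] += count
            distinct["unknown"] += 1
    if genome_mode == "all":
        copies["genome"] += genome_overlap_copies
        distinct["genome"] += genome_overlap_distinct
    result.copies = copies
    result.distinct = distinct
    assert sum(result.gene_counts.values()) == copies["gene_unambiguous"]
    if genome_mode == "remainder":
        assert copies["gene_all"] + copies["genome"] + copies["unknown"] == clean.clean_total
        assert (
            distinct["gene_all"] + distinct["genome"] + distinct["unknown"]
            == clean.distinct_clean
        )
    return result
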