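"""Rendered reports: library tag-analysis statistics and DE summaries.

The library statistics table mirrors the conventional DGE summary: raw and
clean totals, all/unambiguous gene-mapped tags, genome-mapped and unknown tags,
each on total-tag and distinct-tag bases with percentages of clean (or distinct
clean) tags, plus tag-mapped gene counts as a percentage of reference genes.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import pandas as pd

from .cleaning import LibraryStats, format_pct, pct
from .differential import DESummary
from .mapping import MappingResult


def library_report(
    stats: LibraryStats, mapping: MappingResult, n_ref_genes: int
) -> pd.DataFrame:
    """One library's tag-analysis statistics as (metric, value, percent) rows."""
    c = mapping.count_table()
    clean = stats.clean_total
    distinct = stats.distinct_clean
    rows = [
        ("raw_tag", stats.raw_total, None),
        ("distinct_raw_tag", stats.distinct_raw, None),
        ("clean_tag", clean, pct(clean, stats.raw_total)),
        ("distinct_clean_tag", distinct, None),
        ("all_tag_mapping_to_gene", c["gene_all"], pct(c["gene_all"], clean)),
        ("distinct_all_tag_mapping_to_gene", c["distinct_gene_all"],
         pct(c["distinct_gene_all"], distinct)),
        ("unambiguous_tag_mapping_to_gene", c["gene_unambiguous"],
         pct(c["gene_unambiguous"], clean)),
        ("distinct_unambiguous_tag_mapping_to_gene", c["distinct_gene_unambiguous"],
         pct(c["distinct_gene_unambiguous"], distinct)),
        ("all_tag_mapped_genes", c["genes_all"], pct(c["genes_all"], n_ref_genes)),
        ("unambiguous_tag_mapped_genes", c["genes_unambiguous"],
         pct(c["genes_unambiguous"], n_ref_genes)),
        ("mapping_to_genome", c["genome"], pct(c["genome"], clean)),
        ("distinct_mapping_to_genome", c["distinct_genome"],
         pct(c["distinct_genome"], distinct)),
        ("unknown_tag", c["unknown"], pct(c["unknown"], clean)),
        ("distinct_unknown_tag", c["distinct_unknown"],
         pct(c["distinct_unknown"], distinct)),
    ]
    return pd.DataFrame(
        [
            {"metric": name, "value": value, "percent": format_pct(p) if p is not None else ""}
            for name, value, p in rows
        ]
    )


def cleaning_report(stats: LibraryStats) -> pd.DataFrame:
    """Raw-library composition: clean / N / adaptor-only / copy<2 percentages."""
    comps = stats.component_percentages()
    return pd.DataFrame(
        [{"component": k, "percent": format_pct(v)} for k, v in comps.items()]
    )


def de_report(summaries: Sequence[DESummary]) -> pd.DataFrame:
    """Up/down/total DE gene counts per pairwise comparison."""
    return pd.DataFrame(
        [
            {
                "comparison": s.comparison,
                "n_up": s.n_up,
                "n_down": s.n_down,
                "n_total": s.n_total,
            }
            for s in summaries
        ]
    )
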