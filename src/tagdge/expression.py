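"""Per-gene expression: TPM normalization, copy-number distributions, saturation.

TPM here is tag copies per million *clean* tags: TPM_g = copies_g * 10^6 /
clean_total. The denominator is the full clean-tag total of the library (not
only the unambiguous-mapped total), matching how tag libraries are normalized
for cross-library comparison; it is configurable through ``denominator``.
No gene-length correction applies — a transcript contributes one tag per copy
regardless of its length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cleaning import CleanTagTable
from .mapping import map_tag
from .virtual_tags import VirtualTagIndex

#: Copy-number bin edges of the standard library report (last bin open-ended).
DEFAULT_BIN_EDGES = (2, 5, 10, 20, 50, 100, np.inf)


@dataclass
class ExpressionTable:
    """Per-gene unambiguous tag copies and TPM for one library."""

    library_id: str
    counts: pd.Series  # gene -> integer copies
    tpm: pd.Series  # gene -> copies * 1e6 / clean_total
    clean_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"copies": self.counts, "tpm": self.tpm}
        ).rename_axis("gene")


def compute_tpm(
    counts: Mapping[str, int] | pd.Series,
    clean_total: int,
    library_id: str = "",
    gene_universe: Optional[Sequence[str]] = None,
) -> ExpressionTable:
    """Tags-per-million table; genes absent from ``counts`` get 0 copies.

    ``gene_universe`` fixes the row set (e.g. all reference genes) so that two
    libraries share an identical gene index for differential comparison.
    """
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    series = pd.Series(dict(counts), dtype=float)
    if (series < 0).any():
        raise ValueError("counts must be non-negative")
    if gene_universe is not None:
        series = series.reindex(list(gene_universe), fill_value=0.0)
    series = series.sort_index()
    tpm = series * 1e6 / clean_total
    return ExpressionTable(library_id, series.astype(int), tpm, clean_total)


def expression_distribution(
    counts: Mapping[str, int] | pd.Series,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Binned copy-number fractions on the total-copy and distinct-entry bases.

    Bins follow the half-open convention [edge_i, edge_{i+1}); with the default
    edges the categories are [2,5), [5,10), [10,20), [20,50), [50,100) and
    >=100. Each fraction column sums to 1 over entries that fall in some bin
    (an empty table yields zero-filled bins).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 edges")
    values = np.asarray(list(dict(counts).values()) if not isinstance(counts, pd.Series) else counts.to_numpy(), dtype=float)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f">={lo:g}" if np.isinf(hi) else f"[{lo:g},{hi:g})")
    if values.size == 0:
        zero = np.zeros(len(labels))
        return pd.DataFrame({"bin": labels, "total_fraction": zero, "distinct_fraction": zero})
    distinct_counts, _ = np.histogram(values, bins=edges)
    total_counts, _ = np.histogram(values, bins=edges, weights=values)
    # np.histogram closes the last bin; with an inf edge that is the open tail
    distinct_total = distinct_counts.sum()
    copy_total = total_counts.sum()
    return pd.DataFrame(
        {
            "bin": labels,
            "total_fraction": total_counts / copy_total if copy_total else total_counts,
            "distinct_fraction": distinct_counts / distinct_total if distinct_total else distinct_counts,
        }
    )


def saturation_curve(
    clean: CleanTagTable,
    index: VirtualTagIndex,
    sizes: Sequence[int],
    seed: int,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Detected-gene counts under seeded subsampling without replacement.

    For each subsample size, tag copies are drawn without replacement from the
    clean library (multivariate hypergeometric over the distinct-tag copy
    vector), re-mapped, and genes with >= 1 unambiguous tag are counted;
    ``n_replicates`` seeded draws are averaged. Each distinct tag is mapped
    once up front — the subsample only decides which tags are present.
    """
    total = clean.clean_total
    sizes = [int(s) for s in sizes]
    if any(s < 0 or s > total for s in sizes):
        raise ValueError(f"subsample sizes must lie in [0, {total}]")
    tags = list(clean.counts)
    copy_vector = np.array([clean.counts[t] for t in tags], dtype=np.int64)
    tag_gene: list[Optional[str]] = []
    for t in tags:
        category, genes, _ = map_tag(t, index)
        tag_gene.append(next(iter(genes)) if category == "gene_unambiguous" else None)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        detected = []
        for _ in range(n_replicates):
            if size == 0:
                detected.append(0)
                continue
            if size == total:
                draw = copy_vector
            else:
                draw = rng.multivariate_hypergeometric(copy_vector, size, method="marginals")
            present = {g for g, d in zip(tag_gene, draw) if d > 0 and g is not None}
            detected.append(len(present))
        rows.append({"size": size, "mean_detected_genes": float(np.mean(detected))})
    return pd.DataFrame(rows)
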