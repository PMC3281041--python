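"""Hypergeometric term enrichment over differentially expressed gene sets.

With N annotated genes as background, n of them differentially expressed, M
genes carrying a term and m of those differentially expressed, the enrichment
p-value is the upper hypergeometric tail

    p = sum_{i=m}^{min(n, M)} C(M, i) C(N-M, n-i) / C(N, n),

i.e. the probability of drawing at least m term genes when n genes are drawn
from N without replacement. The background is the set of genes with at least
one annotation (configurable). Multiplicity correction defaults to
Benjamini-Hochberg; Bonferroni is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Set

import pandas as pd
from scipy import stats

from .differential import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene-set map plus the annotated background universe."""

    term_to_genes: Mapping[str, FrozenSet[str]]
    universe: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.term_to_genes:
            raise ValueError("annotation has no terms")
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no gene")
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationSet":
        """Build from (gene, term) rows; universe = all annotated genes."""
        mapping: Dict[str, Set[str]] = {}
        universe: Set[str] = set()
        for gene, term in pairs:
            mapping.setdefault(term, set()).add(gene)
            universe.add(gene)
        return cls(
            {t: frozenset(g) for t, g in mapping.items()}, frozenset(universe)
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AnnotationSet":
        """From a two-column frame (gene id, term id); extra columns ignored."""
        gene_col, term_col = table.columns[:2]
        return cls.from_pairs(
            zip(table[gene_col].astype(str), table[term_col].astype(str))
        )


def hypergeom_enrich_term(N: int, n: int, M: int, m: int) -> float:
    """Exact upper-tail enrichment probability P(X >= m) for X ~ Hypergeom."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= M, n <= N; got N={N}, n={n}, M={M}")
    if m < 0 or m > min(n, M):
        raise ValueError(f"need 0 <= m <= min(n, M); got m={m}, n={n}, M={M}")
    if m == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(m - 1, N, M, n)))


def enrich_all_terms(
    annotation: AnnotationSet,
    de_genes: Iterable[str],
    correction: str = "bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term enrichment over the DE set with multiplicity correction.

    DE genes outside the annotated universe are dropped with a logged warning
    (they cannot inform term enrichment). Returns a frame with columns term,
    N, n, M, m, p, corrected_p, significant, sorted by corrected then raw p.
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"correction must be 'bh' or 'bonferroni', got {correction!r}")
    de = set(de_genes)
    outside = de - annotation.universe
    if outside:
        logger.warning(
            "%d DE genes outside the annotated universe dropped (e.g. %s)",
            len(outside), sorted(outside)[:5],
        )
    de &= annotation.universe
    N = len(annotation.universe)
    n = len(de)
    rows = []
    for term, genes in annotation.term_to_genes.items():
        M = len(genes)
        m = len(genes & de)
        rows.append(
            {"term": term, "N": N, "n": n, "M": M, "m": m,
             "p": hypergeom_enrich_term(N, n, M, m)}
        )
    result = pd.DataFrame(rows)
    if correction == "bh":
        result["corrected_p"] = bh_fdr(result["p"].to_numpy())
    else:
        result["corrected_p"] = (result["p"] * len(result)).clip(upper=1.0)
    result["significant"] = result["corrected_p"] < alpha
    return result.sort_values(["corrected_p", "p", "term"]).reset_index(drop=True)
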