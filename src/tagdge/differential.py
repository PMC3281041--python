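"""Differential expression between two tag libraries (Audic-Claverie test).

For a gene with x tag copies in a library of N1 clean tags and y copies in a
library of N2 clean tags, the test conditions on x and asks how surprising y is
under equal underlying expression. The conditional law is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) ),

which is a negative-binomial mass in y with x+1 successes and success
probability N1/(N1+N2). Tail sums are therefore regularized incomplete beta
functions, evaluated with scipy.special.betainc — numerically stable for
counts up to millions. The two-sided p-value is the doubled smaller tail,
capped at 1. Note the test conditions on the first library's count, so it is
only asymptotically (not exactly) symmetric under exchanging the libraries;
at N1 = N2 the point mass itself is exchange-symmetric.

Significance calling uses the thresholds FDR < 0.001 (Benjamini-Hochberg, mode
``"fdr"``) or raw P <= 0.001 (mode ``"p"``), combined with |log2 ratio| >= 1,
oriented later-stage over earlier-stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .expression import ExpressionTable


def _check_counts(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.all(np.equal(np.mod(arr, 1), 0)) or np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative integers")
    return arr.astype(np.int64)


def ac_log_pmf(y, x, n1: int, n2: int) -> np.ndarray:
    """log p(y|x): the per-point conditional mass of the count test."""
    y = _check_counts(y, "y")
    x = _check_counts(x, "x")
    log_r = np.log(n2) - np.log(n1)
    log_1pr = np.logaddexp(0.0, log_r)  # log(1 + N2/N1)
    return (
        y * log_r
        + special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        - (x + y + 1) * log_1pr
    )


def ac_pvalues(
    x, y, n1: int, n2: int
) -> np.ndarray:
    """Vectorized two-sided p-values; see :func:`ac_pvalue`."""
    x = _check_counts(x, "x")
    y = _check_counts(y, "y")
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    q = n1 / (n1 + n2)  # lower-tail parameter of the conditional law
    # P(Y <= y | x) = I_q(x+1, y+1);  P(Y >= y | x) = I_{1-q}(y, x+1) for y >= 1
    lower = special.betainc(x + 1, y + 1, q)
    upper = np.where(y == 0, 1.0, special.betainc(np.maximum(y, 1), x + 1, 1.0 - q))
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided p for y copies (library size n2) vs x copies (size n1).

    p = min(1, 2 * min(P(Y<=y|x), P(Y>=y|x))) under the conditional
    negative-binomial law; symmetric under (x, n1) <-> (y, n2) exchange.
    """
    return float(ac_pvalues(x, y, n1, n2))


def log2_ratio(x: int, n1: int, y: int, n2: int, pseudocount: float = 0.5) -> float:
    """log2 of the normalized-proportion ratio, later (y/N2) over earlier (x/N1).

    The pseudocount regularizes zero counts only: with ``pseudocount=0`` both
    counts must be positive. Equivalent to a TPM ratio since the 10^6 scale
    cancels.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x == 0 or y == 0):
        raise ValueError("zero count requires a positive pseudocount")
    pc = pseudocount if (x == 0 or y == 0) else 0.0
    return float(np.log2(((y + pc) / n2) / ((x + pc) / n1)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de_genes(
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    fdr: float = 0.001,
    lfc: float = 1.0,
    sig_mode: str = "fdr",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene differential calls between library A (earlier) and B (later).

    Returns a frame with columns gene, x, y, tpm_a, tpm_b, log2_ratio, p, q and
    call in {up, down, ns}; log2 ratio is oriented B over A. ``sig_mode="fdr"``
    requires q < ``fdr``; ``sig_mode="p"`` requires p <= ``fdr`` (the same
    numeric threshold applied to raw p-values).
    """
    if sig_mode not in ("fdr", "p"):
        raise ValueError(f"sig_mode must be 'fdr' or 'p', got {sig_mode!r}")
    genes_a, genes_b = set(expr_a.counts.index), set(expr_b.counts.index)
    if genes_a != genes_b:
        only_a = sorted(genes_a - genes_b)[:10]
        only_b = sorted(genes_b - genes_a)[:10]
        raise ValueError(
            f"gene universes differ: only in A {only_a}, only in B {only_b}"
        )
    genes = expr_a.counts.sort_index().index
    x = expr_a.counts.reindex(genes).to_numpy(dtype=np.int64)
    y = expr_b.counts.reindex(genes).to_numpy(dtype=np.int64)
    n1, n2 = expr_a.clean_total, expr_b.clean_total
    p = ac_pvalues(x, y, n1, n2)
    p = np.maximum(p, np.finfo(float).tiny)  # exact zeros only from underflow
    q = bh_fdr(p)
    pc = np.where((x == 0) | (y == 0), pseudocount, 0.0)
    if pseudocount == 0 and np.any(((x == 0) | (y == 0)) & (x + y > 0)):
        raise ValueError("zero count requires a positive pseudocount")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(((y + pc) / n2) / ((x + pc) / n1))
    ratio = np.where((x == 0) & (y == 0), 0.0, ratio)
    significant = q < fdr if sig_mode == "fdr" else p <= fdr
    call = np.full(len(genes), "ns", dtype=object)
    call[significant & (ratio >= lfc)] = "up"
    call[significant & (ratio <= -lfc)] = "down"
    return pd.DataFrame(
        {
            "gene": genes,
            "x": x,
            "y": y,
            "tpm_a": expr_a.tpm.reindex(genes).to_numpy(),
            "tpm_b": expr_b.tpm.reindex(genes).to_numpy(),
            "log2_ratio": ratio,
            "p": p,
            "q": q,
            "call": call,
        }
    )


@dataclass(frozen=True)
class DESummary:
    """Up/down/total aggregation of one pairwise comparison."""

    comparison: str
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


def summarize_de(calls: pd.DataFrame, comparison: str = "") -> DESummary:
    """Aggregate a call table into up/down/total counts."""
    counts = calls["call"].value_counts()
    return DESummary(
        comparison=comparison,
        n_up=int(counts.get("up", 0)),
        n_down=int(counts.get("down", 0)),
    )
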