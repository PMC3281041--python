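"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the count-test tails, exhaustive subset enumeration for the
hypergeometric tail, direct string/array scans for tag extraction and
Hamming-distance mapping.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from fractions import Fraction
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided conditional-test p-value by exact rational summation.

    mass(k) = r^k * C(x+k, k) / (1+r)^(x+k+1) with r = n2/n1; the two-sided p
    doubles the smaller of P(Y<=y) and P(Y>=y), capped at 1.
    """
    r = Fraction(n2, n1)
    mass = Fraction(1, 1) / (1 + r) ** (x + 1)  # k = 0
    lower = mass
    for k in range(1, y + 1):
        mass = mass * r * Fraction(x + k, k) / (1 + r)
        lower += mass
    upper = 1 - (lower - mass)  # P(Y >= y) = 1 - P(Y <= y-1)
    return min(Fraction(1), 2 * min(lower, upper))


def ac_tail_table_exact(
    x_max: int, y_max: int, n1: int, n2: int
) -> Dict[Tuple[int, int], Fraction]:
    """Exact p-values on the full grid x in [0, x_max], y in [0, y_max]."""
    out: Dict[Tuple[int, int], Fraction] = {}
    r = Fraction(n2, n1)
    for x in range(x_max + 1):
        mass = Fraction(1, 1) / (1 + r) ** (x + 1)
        lower = mass
        for y in range(y_max + 1):
            if y > 0:
                mass = mass * r * Fraction(x + y, y) / (1 + r)
                lower += mass
            upper = 1 - (lower - mass)
            out[(x, y)] = min(Fraction(1), 2 * min(lower, upper))
    return out


def hypergeom_overlap_distribution(N: int, n: int) -> Dict[int, Dict[int, int]]:
    """For every prefix size M, the distribution of |draw ∩ first M genes|.

    Enumerates all C(N, n) unordered draws once; overlap with the first-M
    prefix is read off by bisection.
    """
    dist: Dict[int, Dict[int, int]] = {M: {} for M in range(N + 1)}
    for draw in combinations(range(N), n):
        for M in range(N + 1):
            overlap = bisect_left(draw, M)
            dist[M][overlap] = dist[M].get(overlap, 0) + 1
    return dist


def hypergeom_upper_tail_exact(N: int, n: int, M: int, m: int) -> Fraction:
    """P(overlap >= m) by exhaustive enumeration of all n-subsets of N genes."""
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if bisect_left(draw, M) >= m:
            hits += 1
    return Fraction(hits, total)


def scan_catg_windows(sequence: str, tag_length: int = 21) -> List[str]:
    """All N-free CATG+17 windows by a direct positional scan, 3' to 5'."""
    sequence = sequence.upper()
    windows = []
    for i in range(len(sequence) - tag_length, -1, -1):
        w = sequence[i : i + tag_length]
        if w.startswith("CATG") and "N" not in w:
            windows.append(w)
    return windows


def encode_tags(tags: Sequence[str], anchor_len: int = 4) -> np.ndarray:
    """Variable regions of 21-nt tags as a (n, 17) uint8 code matrix."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = np.frombuffer("".join(t[anchor_len:] for t in tags).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(tags), -1)


def brute_force_map(
    tag: str,
    entries: Sequence[str],
    entry_genes: Sequence[frozenset],
    genome: Optional[Sequence[str]] = None,
) -> Tuple[str, frozenset, Optional[int]]:
    """Classify one tag by an all-pairs Hamming scan over the 17-nt regions."""
    def ham(a: str, b: str) -> int:
        return sum(u != v for u, v in zip(a[4:], b[4:]))

    best = None
    genes: set = set()
    for entry, owners in zip(entries, entry_genes):
        d = ham(tag, entry)
        if d > 1:
            continue
        if best is None or d < best:
            best, genes = d, set(owners)
        elif d == best:
            genes |= set(owners)
    if best is not None:
        cat = "gene_unambiguous" if len(genes) == 1 else "gene_all"
        return cat, frozenset(genes), best
    if genome:
        gbest = min((ham(tag, g) for g in genome), default=99)
        if gbest <= 1:
            return "genome", frozenset(), gbest
    return "unknown", frozenset(), None


def brute_force_map_many(
    tags: Sequence[str],
    entries: Sequence[str],
    entry_genes: Sequence[frozenset],
    genome: Optional[Sequence[str]] = None,
) -> List[Tuple[str, frozenset, Optional[int]]]:
    """Vectorized all-pairs Hamming classification of many tags at once."""
    T = encode_tags(tags)
    E = encode_tags(entries)
    G = encode_tags(genome) if genome else None
    results = []
    chunk = 500
    for start in range(0, len(tags), chunk):
        sub = T[start : start + chunk]
        dist = (sub[:, None, :] != E[None, :, :]).sum(axis=2)
        gdist = (sub[:, None, :] != G[None, :, :]).sum(axis=2) if G is not None else None
        for i in range(sub.shape[0]):
            row = dist[i]
            best = int(row.min()) if row.size else 99
            if best <= 1:
                genes: set = set()
                for j in np.nonzero(row == best)[0]:
                    genes |= set(entry_genes[j])
                cat = "gene_unambiguous" if len(genes) == 1 else "gene_all"
                results.append((cat, frozenset(genes), best))
                continue
            if gdist is not None and gdist[i].size and int(gdist[i].min()) <= 1:
                results.append(("genome", frozenset(), int(gdist[i].min())))
            else:
                results.append(("unknown", frozenset(), None))
    return results


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Textbook equal-variance two-sample t-test (statistic, two-sided p)."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t_stat), na + nb - 2)
    return t_stat, p
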