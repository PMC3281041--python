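"""Ground-truth simulator for NlaIII/MmeI tag sequencing.

Emulates the wet protocol end to end: random reference transcripts, stage-wise
expression profiles with a known set of differentially expressed genes, and raw
21-nt tag libraries drawn from the 3'-most CATG+17-nt tag of each sampled
transcript, contaminated with adaptor-only reads, N-containing reads and
substitution-error variants. Every emitted record carries a provenance label,
so downstream cleaning, mapping and differential-expression calls can be scored
against truth.

Protocol asymmetry worth noting: the physical library samples only the 3'-most
CATG site of each transcript (bead precipitation retains the 3' fragment), while
the reference index enumerates every site. Errors hit only the 17-nt variable
region — a read with a corrupted CATG anchor would not be recognized as a tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cleaning import RawTagLibrary
from .virtual_tags import ANCHOR, TAG_LENGTH, VARIABLE_LENGTH, most_3prime_tag

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_STAGES = ("-72h", "0h", "72h")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults are desk-scale: 2000 genes and 5x10^5 tags per library keep a full
    pipeline run in seconds while leaving hundreds of expected copies per gene,
    the regime in which the exact count test is informative. Artifact rates
    (1% adaptor-only, 0.5% N-containing) put the clean-tag fraction near the
    ~98% a well-behaved library shows. de_fold_change is the fold applied to
    differential genes between stages; error_rate is the per-base substitution
    probability over the 17-nt variable region.
    """

    n_genes: int = 2000
    transcript_length_range: Tuple[int, int] = (300, 2000)
    gc_content: float = 0.4
    n_libraries: int = 3
    base_mean_expression: float = 1.0
    de_fraction: float = 0.1
    de_fold_change: float = 4.0
    depth: int = 500_000
    error_rate: float = 0.01
    adaptor_only_rate: float = 0.01
    n_tag_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length_range
        if hi < lo:
            raise ValueError(f"transcript_length_range max < min: {self.transcript_length_range}")
        if lo < TAG_LENGTH + 4:
            raise ValueError(f"transcripts must be at least {TAG_LENGTH + 4} nt")
        if self.n_genes < 1 or self.depth < 1 or self.n_libraries < 1:
            raise ValueError("n_genes, depth and n_libraries must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_fold_change < 1.0:
            raise ValueError("de_fold_change must be >= 1")
        for name in ("error_rate", "adaptor_only_rate", "n_tag_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.adaptor_only_rate + self.n_tag_rate >= 1.0:
            raise ValueError("artifact rates must sum to < 1")

    def library_ids(self) -> List[str]:
        if self.n_libraries == 3:
            return list(DEFAULT_STAGES)
        return [f"lib{i + 1}" for i in range(self.n_libraries)]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``expression`` is gene x library expected relative abundance (columns sum
    to 1). ``de_labels`` is gene x library-pair in {up, down, null}, oriented
    later-over-earlier. ``provenance`` maps library id to a table with one row
    per (tag sequence, origin) combination; origins are ``gene`` (error-free
    copy of the source gene's 3'-most tag), ``error_variant``, ``n_contaminated``
    and ``adaptor_only``; counts per library sum to the configured depth.
    """

    expression: pd.DataFrame
    de_labels: pd.DataFrame
    provenance: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def provenance_totals(self, library_id: str) -> Dict[str, int]:
        df = self.provenance[library_id]
        return df.groupby("origin")["count"].sum().to_dict()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substream per operation so each op is deterministic on its own
    return np.random.default_rng([config.seed, stream])


def _codes_to_strings(codes: np.ndarray) -> List[str]:
    letters = _BASE_ARR[codes]
    n = codes.shape[1]
    return [bytes(row).decode() for row in letters.view(f"S{n}").ravel()]


def simulate_transcriptome(config: SimConfig) -> Dict[str, str]:
    """Random reference transcripts over ACGT at the configured GC content.

    Returns an ordered gene-id -> sequence map; use :func:`taggable_flags` for
    the per-gene taggability report (>=1 CATG site with >=17 nt downstream).
    """
    rng = _rng(config, 1)
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    p_gc = config.gc_content / 2.0
    p_at = (1.0 - config.gc_content) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])  # A, C, G, T
    width = int(math.ceil(math.log10(config.n_genes + 1)))
    genes: Dict[str, str] = {}
    for i, length in enumerate(lengths):
        codes = rng.choice(4, size=int(length), p=probs).astype(np.uint8)
        genes[f"G{i + 1:0{width}d}"] = "".join("ACGT"[c] for c in codes)
    return genes


def taggable_flags(genes: Mapping[str, str]) -> Dict[str, bool]:
    """Per-gene flag: does the transcript yield any CATG+17-nt tag at all?"""
    return {g: most_3prime_tag(seq) is not None for g, seq in genes.items()}


def _pair_label(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def simulate_expression_profiles(
    config: SimConfig, genes: Mapping[str, str]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-wise expected relative abundances plus truth DE labels.

    Baseline abundance per gene is exponential (Gamma shape 1) around
    ``base_mean_expression``, giving the long right tail count libraries show.
    A ``de_fraction`` of genes changes by ``de_fold_change`` (direction up or
    down with equal probability) in every library after the first; remaining
    genes keep identical expected abundance. Columns are normalized to sum to 1.
    Labels are oriented later-over-earlier for each library pair.
    """
    if config.n_libraries < 2 and config.de_fraction > 0:
        raise ValueError("DE structure needs at least two libraries")
    rng = _rng(config, 2)
    gene_ids = list(genes)
    n = len(gene_ids)
    base = rng.gamma(shape=1.0, scale=config.base_mean_expression, size=n)
    base = np.maximum(base, 1e-9 * config.base_mean_expression)
    is_de = rng.random(n) < config.de_fraction
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    direction[~is_de] = 0.0
    lib_ids = config.library_ids()
    expr = np.tile(base[:, None], (1, config.n_libraries))
    fold = config.de_fold_change ** direction
    for j in range(1, config.n_libraries):
        expr[:, j] = base * fold
    expr = expr / expr.sum(axis=0, keepdims=True)
    expression = pd.DataFrame(expr, index=gene_ids, columns=lib_ids)

    pairs = [
        (lib_ids[i], lib_ids[j])
        for i in range(config.n_libraries)
        for j in range(i + 1, config.n_libraries)
    ]
    labels = {}
    for a, b in pairs:
        ia, ib = lib_ids.index(a), lib_ids.index(b)
        col = np.full(n, "null", dtype=object)
        if ia == 0 and ib > 0:  # fold change steps in after the first stage
            col[direction > 0] = "up"
            col[direction < 0] = "down"
        labels[_pair_label(a, b)] = col
    de_labels = pd.DataFrame(labels, index=gene_ids)
    return expression, de_labels


def _mutate_tags(
    rng: np.random.Generator, codes: np.ndarray, error_rate: float
) -> np.ndarray:
    """Apply >=1 substitution to each 17-nt variable region in ``codes``.

    The per-read error count is drawn from Binomial(17, e) conditioned on >= 1,
    positions uniformly without replacement, substituted base uniform over the
    three alternatives — the exact conditional law of independent per-base
    errors given that the read is erroneous at all.
    """
    n = codes.shape[0]
    if n == 0:
        return codes
    k_support = np.arange(1, VARIABLE_LENGTH + 1)
    log_pmf = (
        np.log([math.comb(VARIABLE_LENGTH, int(k)) for k in k_support])
        + k_support * math.log(error_rate)
        + (VARIABLE_LENGTH - k_support) * math.log1p(-error_rate)
    )
    pmf = np.exp(log_pmf - log_pmf.max())
    pmf /= pmf.sum()
    n_errors = rng.choice(k_support, size=n, p=pmf)
    # uniform k-subset of positions per row via random-key argsort
    keys = rng.random((n, VARIABLE_LENGTH))
    order = np.argsort(keys, axis=1)
    out = codes.copy()
    rows = np.arange(n)
    for k in np.unique(n_errors):
        mask = n_errors == k
        pos = order[mask, :k]
        r = np.repeat(rows[mask], k)
        c = pos.ravel()
        shift = rng.integers(1, 4, size=c.size).astype(np.uint8)
        out[r, c] = (out[r, c] + shift) % 4
    return out


def simulate_raw_tags(
    config: SimConfig,
    genes: Mapping[str, str],
    expression: pd.DataFrame,
) -> Tuple[Dict[str, RawTagLibrary], SimTruth]:
    """Draw ``depth`` raw records per library with per-record provenance.

    Each record is, with probability ``adaptor_only_rate``, an adaptor-only
    artifact; with probability ``n_tag_rate`` an N-containing read; otherwise a
    copy of a gene's 3'-most CATG+17-nt tag (gene sampled proportional to
    abundance among taggable genes), possibly carrying substitution errors in
    the variable region at ``error_rate`` per base.
    """
    tag_by_gene = {g: most_3prime_tag(seq) for g, seq in genes.items()}
    taggable = [g for g, t in tag_by_gene.items() if t is not None]
    if not taggable:
        raise SimulationError(
            "no taggable gene: every transcript lacks a CATG site with 17 nt downstream"
        )
    lib_ids = list(expression.columns)
    code_of = {b: i for i, b in enumerate("ACGT")}
    var_codes = np.array(
        [[code_of[b] for b in tag_by_gene[g][len(ANCHOR):]] for g in taggable],
        dtype=np.uint8,
    )
    p_err_read = 1.0 - (1.0 - config.error_rate) ** VARIABLE_LENGTH

    libraries: Dict[str, RawTagLibrary] = {}
    provenance: Dict[str, pd.DataFrame] = {}
    for li, lib in enumerate(lib_ids):
        rng = _rng(config, 10 + li)
        abundance = expression[lib].reindex(taggable).to_numpy(dtype=float)
        if abundance.sum() <= 0:
            raise SimulationError(f"library {lib!r}: no taggable gene has nonzero abundance")
        abundance = abundance / abundance.sum()

        n_adaptor, n_ncontam, n_gene = rng.multinomial(
            config.depth,
            [config.adaptor_only_rate, config.n_tag_rate,
             1.0 - config.adaptor_only_rate - config.n_tag_rate],
        )
        gene_counts = rng.multinomial(int(n_gene), abundance)
        err_counts = (
            rng.binomial(gene_counts, p_err_read)
            if config.error_rate > 0
            else np.zeros_like(gene_counts)
        )
        clean_counts = gene_counts - err_counts

        tags: Dict[str, int] = {}
        rows: List[Tuple[str, str, str, int]] = []  # tag, origin, source_gene, count
        for gi in np.nonzero(clean_counts)[0]:
            g = taggable[gi]
            t = tag_by_gene[g]
            tags[t] = tags.get(t, 0) + int(clean_counts[gi])
            rows.append((t, "gene", g, int(clean_counts[gi])))

        if err_counts.sum() > 0:
            src = np.repeat(np.arange(len(taggable)), err_counts)
            mutated = _mutate_tags(rng, var_codes[src], config.error_rate)
            variants = _codes_to_strings(mutated)
            per_variant: Dict[Tuple[str, str], int] = {}
            for gi, var in zip(src, variants):
                key = (ANCHOR + var, taggable[gi])
                per_variant[key] = per_variant.get(key, 0) + 1
            for (t, g), c in per_variant.items():
                tags[t] = tags.get(t, 0) + c
                rows.append((t, "error_variant", g, c))

        if n_ncontam > 0:
            codes = rng.integers(0, 4, size=(int(n_ncontam), VARIABLE_LENGTH)).astype(np.uint8)
            n_ns = rng.integers(1, 4, size=int(n_ncontam))
            keys = rng.random((int(n_ncontam), VARIABLE_LENGTH))
            order = np.argsort(keys, axis=1)
            raw_strings = _codes_to_strings(codes)
            per_tag: Dict[str, int] = {}
            for i, s in enumerate(raw_strings):
                chars = list(s)
                for pos in order[i, : n_ns[i]]:
                    chars[pos] = "N"
                t = ANCHOR + "".join(chars)
                per_tag[t] = per_tag.get(t, 0) + 1
            for t, c in per_tag.items():
                tags[t] = tags.get(t, 0) + c
                rows.append((t, "n_contaminated", "", c))

        if n_adaptor > 0:
            rows.append(("", "adaptor_only", "", int(n_adaptor)))

        libraries[lib] = RawTagLibrary(lib, tags, adaptor_only=int(n_adaptor))
        prov = pd.DataFrame(rows, columns=["tag", "origin", "source_gene", "count"])
        assert int(prov["count"].sum()) == config.depth
        provenance[lib] = prov

    # DE labels are not re-derived here; callers pair this with the profiles op
    truth = SimTruth(expression=expression.copy(), de_labels=pd.DataFrame(index=expression.index),
                     provenance=provenance)
    return libraries, truth


def simulate_experiment(config: SimConfig):
    """Convenience wrapper running all three simulation stages.

    Returns ``(genes, libraries, truth)`` where ``truth`` carries the expression
    matrix, DE labels and per-library tag provenance.
    """
    genes = simulate_transcriptome(config)
    expression, de_labels = simulate_expression_profiles(config, genes)
    libraries, truth = simulate_raw_tags(config, genes, expression)
    truth.de_labels = de_labels
    return genes, libraries, truth
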