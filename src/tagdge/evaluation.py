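"""Scoring pipeline output against simulator ground truth.

Utilities for the package's self-validation experiments: run the analysis
stages on a simulated two-library experiment and compare the differential
calls with the truth labels (sensitivity, empirical false discovery rate,
null p-value calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .cleaning import clean_raw_tags
from .differential import call_de_genes
from .expression import compute_tpm
from .mapping import map_library
from .simulate import SimConfig, simulate_experiment
from .virtual_tags import build_index, most_3prime_tag


@dataclass
class DERecovery:
    """Differential calls joined with truth for one library pair."""

    calls: pd.DataFrame  # call table plus truth_label, taggable, expected_mean_count
    clean_totals: Dict[str, int]

    def sensitivity(self, min_expected_count: float = 0.0) -> Optional[float]:
        """Fraction of true DE genes called in the correct direction.

        Restricted to taggable genes whose expected tag count (mean of the two
        libraries) is at least ``min_expected_count`` — genes the library depth
        can actually inform.
        """
        df = self.calls
        eligible = (
            (df["truth_label"] != "null")
            & df["taggable"]
            & (df["expected_mean_count"] >= min_expected_count)
        )
        n = int(eligible.sum())
        if n == 0:
            return None
        correct = (df.loc[eligible, "call"] == df.loc[eligible, "truth_label"]).sum()
        return float(correct / n)

    def empirical_fdr(self) -> Optional[float]:
        """Fraction of called genes that are truly null."""
        called = self.calls[self.calls["call"] != "ns"]
        if len(called) == 0:
            return None
        return float((called["truth_label"] == "null").mean())

    def null_pvalue_fraction(self, threshold: float = 0.001) -> float:
        """Fraction of truly null taggable genes with p <= threshold."""
        null = self.calls[(self.calls["truth_label"] == "null") & self.calls["taggable"]]
        return float((null["p"] <= threshold).mean())

    @property
    def n_null_taggable(self) -> int:
        return int(((self.calls["truth_label"] == "null") & self.calls["taggable"]).sum())


def run_de_recovery(
    config: SimConfig,
    fdr: float = 0.001,
    lfc: float = 1.0,
    sig_mode: str = "fdr",
) -> DERecovery:
    """Simulate a two-library experiment, run the pipeline stages, join truth."""
    if config.n_libraries != 2:
        raise ValueError("DE recovery experiments use exactly two libraries")
    genes, libraries, truth = simulate_experiment(config)
    index = build_index(genes)
    universe = sorted(genes)
    expr = {}
    clean_totals = {}
    for lib_id, raw in libraries.items():
        table, _ = clean_raw_tags(raw)
        mapping = map_library(table, index)
        clean_totals[lib_id] = table.clean_total
        expr[lib_id] = compute_tpm(
            mapping.gene_counts, table.clean_total, lib_id, gene_universe=universe
        )
    a, b = truth.expression.columns
    calls = call_de_genes(expr[a], expr[b], fdr=fdr, lfc=lfc, sig_mode=sig_mode)
    calls = calls.set_index("gene")
    calls["truth_label"] = truth.de_labels.iloc[:, 0].reindex(calls.index)
    calls["taggable"] = [most_3prime_tag(genes[g]) is not None for g in calls.index]
    expected = truth.expression.mul(config.depth)
    calls["expected_mean_count"] = expected.mean(axis=1).reindex(calls.index)
    return DERecovery(calls=calls.reset_index(), clean_totals=clean_totals)
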