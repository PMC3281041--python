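"""Audic-Claverie test, BH step-up, and the up/down/ns calling logic."""

import numpy as np
import pandas as pd
import pytest

from oracles import ac_pvalue_exact
from tagdge import ac_pvalue, bh_fdr, call_de_genes, compute_tpm, log2_ratio, summarize_de
from tagdge.differential import ac_log_pmf


class TestAcPvalue:
    def test_zero_zero_equal_libraries(self):
        assert ac_pvalue(0, 0, 100_000, 100_000) == 1.0
        # per-point mass p(0|0) is exactly (1/2)^1
        assert np.isclose(np.exp(ac_log_pmf(0, 0, 10, 10)), 0.5)

    def test_point_mass_symmetric_for_equal_libraries(self):
        # with N1 = N2 the conditional mass itself is exchange-symmetric,
        # even though the tail-based p (which conditions on x) is not
        for x, y in [(0, 3), (2, 9), (15, 4)]:
            assert np.isclose(
                ac_log_pmf(y, x, 10**5, 10**5), ac_log_pmf(x, y, 10**5, 10**5)
            )

    def test_exchange_near_symmetry_at_large_counts(self):
        # conditioning on x vs on y converges for well-populated genes
        rng = np.random.default_rng(0)
        for _ in range(30):
            x, y = int(rng.integers(200, 2000)), int(rng.integers(200, 2000))
            n1, n2 = int(rng.integers(10**5, 10**6)), int(rng.integers(10**5, 10**6))
            a, b = ac_pvalue(x, y, n1, n2), ac_pvalue(y, x, n2, n1)
            if min(a, b) > 1e-12:  # both tails resolved above float noise
                assert abs(np.log(a) - np.log(b)) < 0.2 * abs(np.log(min(a, b))) + 0.3

    @pytest.mark.parametrize("n1,n2", [(10**5, 10**5), (10**5, 2 * 10**5)])
    def test_matches_exact_rational_oracle(self, n1, n2):
        for x in range(0, 13):
            for y in range(0, 13):
                exact = float(ac_pvalue_exact(x, y, n1, n2))
                got = ac_pvalue(x, y, n1, n2)
                assert abs(got - exact) <= 1e-9 * exact

    def test_point_masses_normalize(self):
        for x in (0, 5, 50):
            y = np.arange(0, 5000)
            total = np.exp(ac_log_pmf(y, x, 10**5, 2 * 10**5)).sum()
            assert abs(total - 1.0) < 1e-9

    def test_large_counts_stable(self):
        p = ac_pvalue(10**6, 10**6, 5 * 10**6, 5 * 10**6)
        assert 0.9 < p <= 1.0
        p_diff = ac_pvalue(10**6, 10**6 + 10**4, 5 * 10**6, 5 * 10**6)
        assert 0 < p_diff < 1e-6

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_pvalue(1.5, 2, 100, 100)
        with pytest.raises(ValueError):
            ac_pvalue(-1, 2, 100, 100)


class TestLog2Ratio:
    def test_doubling(self):
        assert log2_ratio(10, 1000, 20, 1000, pseudocount=0) == 1.0

    def test_equal_counts(self):
        assert log2_ratio(7, 1000, 7, 1000, pseudocount=0) == 0.0

    def test_pseudocount_on_zero(self):
        got = log2_ratio(0, 10**6, 8, 10**6, pseudocount=0.5)
        assert np.isclose(got, np.log2(8.5 / 0.5))  # ~4.087

    def test_zero_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(0, 1000, 5, 1000, pseudocount=0)

    def test_library_size_normalization(self):
        # same counts, half the depth in B => proportion doubles
        assert log2_ratio(10, 2000, 10, 1000, pseudocount=0) == 1.0


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_returned_in_input_order(self):
        p = [0.04, 0.001, 0.5, 0.01]
        q = bh_fdr(p)
        m = len(p)
        # direct step-up on the sorted vector, mapped back
        order = np.argsort(p)
        expected_sorted = np.minimum.accumulate(
            (np.array(p)[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        assert np.allclose(q, expected)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=300)
        _, q_ref, _, _ = statsmodels.multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


def _expr(counts, total, lib=""):
    return compute_tpm(counts, total, lib)


class TestCallDeGenes:
    def test_identical_libraries_no_calls(self):
        counts = {f"g{i}": 10 * (i + 1) for i in range(20)}
        calls = call_de_genes(_expr(counts, 10**5, "a"), _expr(counts, 10**5, "b"))
        s = summarize_de(calls)
        assert s.n_up == 0 and s.n_down == 0

    def test_strong_fold_called_up_small_fold_ns(self):
        n = 10**6
        a = {"big_change": 100, "small_change": 1000, "flat": 500}
        b = {"big_change": 450, "small_change": 1500, "flat": 500}
        calls = call_de_genes(_expr(a, n, "a"), _expr(b, n, "b")).set_index("gene")
        # both changes are wildly significant; only the >=2-fold one passes |lfc|>=1
        assert calls.loc["big_change", "q"] < 0.001
        assert calls.loc["small_change", "q"] < 0.001
        assert calls.loc["big_change", "call"] == "up"
        assert calls.loc["small_change", "call"] == "ns"
        assert calls.loc["flat", "call"] == "ns"

    def test_p_mode_uses_raw_pvalues(self):
        n = 10**6
        a = {f"g{i}": 50 for i in range(50)} | {"hit": 20}
        b = {f"g{i}": 50 for i in range(50)} | {"hit": 80}
        expr_a, expr_b = _expr(a, n, "a"), _expr(b, n, "b")
        p_calls = call_de_genes(expr_a, expr_b, sig_mode="p").set_index("gene")
        fdr_calls = call_de_genes(expr_a, expr_b, sig_mode="fdr").set_index("gene")
        hit_p = p_calls.loc["hit", "p"]
        assert (p_calls.loc["hit", "call"] == "up") == (hit_p <= 0.001)
        # q >= p always, so fdr mode can only be more conservative
        assert fdr_calls.loc["hit", "q"] >= hit_p

    def test_exchange_antisymmetry(self):
        """Swapping libraries negates every log2 ratio exactly and flips the
        direction of every decisive call (the conditional p is orientation-
        dependent, so only threshold-straddling genes may change status)."""
        rng = np.random.default_rng(2)
        a = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, size=100))}
        b = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, size=100))}
        ea, eb = _expr(a, 10**5, "a"), _expr(b, 10**5, "b")
        fwd = call_de_genes(ea, eb).set_index("gene")
        rev = call_de_genes(eb, ea).set_index("gene")
        assert np.allclose(fwd["log2_ratio"], -rev["log2_ratio"])
        flip = {"up": "down", "down": "up", "ns": "ns"}
        decisive = (
            ((fwd["q"] < 1e-4) | (fwd["q"] > 1e-2))
            & ((rev["q"] < 1e-4) | (rev["q"] > 1e-2))
        )
        assert decisive.sum() > 50  # the check must actually bite
        for g in fwd.index[decisive]:
            assert rev.loc[g, "call"] == flip[fwd.loc[g, "call"]]

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universes differ"):
            call_de_genes(_expr({"a": 5}, 100, "x"), _expr({"b": 5}, 100, "y"))

    def test_q_never_below_p(self):
        rng = np.random.default_rng(3)
        a = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 300, size=200))}
        b = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 300, size=200))}
        calls = call_de_genes(_expr(a, 10**5, "a"), _expr(b, 10**5, "b"))
        assert (calls["q"] >= calls["p"] - 1e-15).all()

    def test_summary_totals(self):
        calls = pd.DataFrame({"call": ["up"] * 3 + ["down"] * 2 + ["ns"] * 5})
        s = summarize_de(calls, "a_vs_b")
        assert (s.n_up, s.n_down, s.n_total) == (3, 2, 5)
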