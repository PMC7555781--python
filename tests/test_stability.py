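"""Exact count test, FDR adjustment and stability classification rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from degradome.stability import (
    adjust_fdr,
    classify_stability,
    estimate_dispersion,
    exact_count_test,
)


def binomial_oracle(a: int, b: int) -> float:
    """Brute-force two-sided conditional binomial test at p = 1/2."""
    n = a + b
    pmf = binom.pmf(np.arange(n + 1), n, 0.5)
    return float(pmf[pmf <= pmf[a] * (1 + 1e-12)].sum())


class TestExactCountTest:
    def test_perfect_symmetry_gives_p_one(self):
        p = exact_count_test([50, 50], [50, 50], [1e6, 1e6], [1e6, 1e6], 0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_imbalance(self):
        p = exact_count_test([0, 0], [200, 200], [1e6, 1e6], [1e6, 1e6], 0.0)
        assert p < 1e-6

    def test_all_zero_counts_give_p_one(self):
        assert exact_count_test([0, 0], [0, 0], [1e6, 1e6], [1e6, 1e6], 0.0) == 1.0

    @pytest.mark.parametrize("a,b", [(0, 10), (3, 7), (30, 70), (55, 45), (100, 100)])
    def test_dispersion_zero_matches_binomial_enumeration(self, a, b):
        p = exact_count_test(
            [a / 2, a / 2], [b / 2, b / 2], [1e6, 1e6], [1e6, 1e6], 0.0
        )
        assert p == pytest.approx(binomial_oracle(a, b), rel=1e-9)

    def test_library_size_equalization(self):
        # same relative abundance at unequal depths -> no signal
        p = exact_count_test([100, 100], [200, 200], [1e6, 1e6], [2e6, 2e6], 0.0)
        assert p > 0.5

    def test_dispersion_widens_the_null(self):
        args = ([130, 130], [70, 70], [1e6, 1e6], [1e6, 1e6])
        assert exact_count_test(*args, 0.5) > exact_count_test(*args, 0.0)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 300, size=2)
            b = rng.integers(0, 300, size=2)
            p = exact_count_test(a, b, [1e6, 1.3e6], [0.8e6, 1e6], 0.1)
            assert 0.0 < p <= 1.0


class TestAdjustFdr:
    def test_single_value_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert adjust_fdr([]).size == 0

    def test_sorted_fdr_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        fdr = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)


def _abundance_frame(rna, pare, lengths=None, totals=(10_000, 10_000)):
    n = len(rna)
    lengths = lengths or [1000] * n
    df = pd.DataFrame(
        {
            "transcript_id": [f"T{i}" for i in range(n)],
            "length": lengths,
            "rna_count_r1": [r[0] for r in rna],
            "rna_count_r2": [r[1] for r in rna],
            "pare_count_r1": [p[0] for p in pare],
            "pare_count_r2": [p[1] for p in pare],
        }
    )
    for r in (1, 2):
        df[f"fpkm_r{r}"] = df[f"rna_count_r{r}"] * 1e9 / (
            np.array(lengths) * totals[0]
        )
        df[f"dpkm_r{r}"] = df[f"pare_count_r{r}"] * 1e9 / (
            np.array(lengths) * totals[1]
        )
    df.attrs["rna_totals"] = [totals[0]] * 2
    df.attrs["pare_totals"] = [totals[1]] * 2
    return df


class TestClassifyStability:
    def test_filter_rules(self):
        # T0: strong RNA excess -> stable; T1: strong decay excess ->
        # unstable; T2: 2-fold change only -> neither (fold-change filter);
        # T3: balanced -> neither
        df = _abundance_frame(
            rna=[(800, 820), (10, 12), (200, 210), (100, 100)],
            pare=[(10, 12), (800, 820), (100, 95), (100, 100)],
        )
        res, summary = classify_stability(df, dispersion=0.0)
        assert list(res["class"]) == ["stable", "unstable", "neither", "neither"]
        assert summary.n_stable == 1 and summary.n_unstable == 1

    def test_abundance_filter_blocks_rare_transcripts(self):
        df = _abundance_frame(
            rna=[(60, 60)], pare=[(0, 0)], lengths=[1000], totals=(10**8, 10**8)
        )
        # fpkm = 60e9/(1000*1e8) = 0.6 < 1 and dpkm = 0 -> fails abundance
        res, _ = classify_stability(df, dispersion=0.0)
        assert not res["passes_abundance"].iloc[0]
        assert res["class"].iloc[0] == "neither"

    def test_pseudocount_only_when_one_side_zero(self):
        df = _abundance_frame(rna=[(400, 400)], pare=[(0, 0)])
        res, _ = classify_stability(df, dispersion=0.0)
        expected = np.log2((800 / 20_000) / (0.5 / 20_000))
        assert res["log2fc"].iloc[0] == pytest.approx(expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        rna = [tuple(rng.integers(0, 500, size=2)) for _ in range(30)]
        pare = [tuple(rng.integers(0, 500, size=2)) for _ in range(30)]
        df = _abundance_frame(rna=rna, pare=pare)
        res1, _ = classify_stability(df, dispersion=0.05)
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled.attrs = dict(df.attrs)
        res2, _ = classify_stability(shuffled, dispersion=0.05)
        merged = res1.merge(res2, on="transcript_id", suffixes=("_a", "_b"))
        assert (merged["class_a"] == merged["class_b"]).all()
        np.testing.assert_allclose(merged["fdr_a"], merged["fdr_b"])


class TestEstimateDispersion:
    def test_recovers_planted_dispersion_roughly(self):
        rng = np.random.default_rng(4)
        phi = 0.1
        mu = rng.uniform(200, 2000, size=2000)
        counts = rng.poisson(
            rng.gamma(1 / phi, phi * mu[:, None], size=(2000, 2))
        )
        est = estimate_dispersion(counts, [1e6, 1e6])
        assert est == pytest.approx(phi, rel=0.5)

    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(500.0, size=(2000, 2))
        assert estimate_dispersion(counts, [1e6, 1e6]) < 0.01
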