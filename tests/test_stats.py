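"""Correlation/normality machinery, validation comparison and grid study."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cranioflow.stats import (
    correlation_analysis,
    grid_independence,
    icc_stiffness_analysis,
    validation_compare,
)
from cranioflow.synthetic import sample_independent_metric_table


class TestCorrelation:
    def test_perfect_linear_relationship(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = correlation_analysis(x, 2 * x + 1)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.pearson_verdict == "significant"

    def test_monotone_decreasing_nonlinear(self):
        x = np.linspace(0.0, 3.0, 8)
        rep = correlation_analysis(x, np.exp(-x))
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert abs(rep.pearson_r) < 1.0

    def test_spearman_matches_rank_formula_no_ties(self):
        rng = np.random.default_rng(3)
        x = rng.permutation(5).astype(float)
        y = rng.normal(size=5)
        rep = correlation_analysis(x, y)
        # brute-force rank oracle: 1 - 6 sum d^2 / (n (n^2 - 1))
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = float(((rx - ry) ** 2).sum())
        n = 5
        assert rep.spearman_rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)

    def test_exact_permutation_p_matches_direct_enumeration(self):
        x = np.array([0.3, 1.2, 2.7, 3.1, 4.9])
        y = np.array([1.1, 0.2, 3.0, 2.2, 4.4])
        rep = correlation_analysis(x, y)
        rho_obs = sps.spearmanr(x, y).statistic
        count = 0
        perms = list(itertools.permutations(y))
        for p in perms:
            if abs(sps.spearmanr(x, p).statistic) >= abs(rho_obs) - 1e-12:
                count += 1
        assert rep.spearman_p == pytest.approx(count / len(perms), abs=1e-12)
        assert "spearman_p: exact permutation" in rep.flags

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        rep = correlation_analysis(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert rep.spearman_rho == pytest.approx(sps.pearsonr(rx, ry).statistic, abs=1e-12)

    def test_pearson_affine_invariance_and_rank_monotone_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = rng.normal(size=25) + x
        base = correlation_analysis(x, y)
        aff = correlation_analysis(3.0 * x - 7.0, y)
        assert aff.pearson_r == pytest.approx(base.pearson_r, abs=1e-12)
        mono = correlation_analysis(np.exp(x), y)  # strictly increasing map
        assert mono.spearman_rho == pytest.approx(base.spearman_rho, abs=1e-12)

    def test_constant_input_flagged_not_raised(self):
        rep = correlation_analysis([1.0, 1.0, 1.0, 1.0], [0.1, 0.4, 0.2, 0.9])
        assert np.isnan(rep.pearson_r)
        assert rep.pearson_verdict == "undefined"
        assert any("constant_input" in f for f in rep.flags)

    def test_verdict_consistent_with_alpha(self):
        x = np.linspace(0, 1, 20)
        rng = np.random.default_rng(0)
        y = x + rng.normal(0, 0.05, 20)
        rep = correlation_analysis(x, y, alpha=0.05)
        assert (rep.pearson_p < 0.05) == (rep.pearson_verdict == "significant")
        d = rep.to_dict()
        assert d["pearson_verdict"] == rep.pearson_verdict

    def test_too_short_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            correlation_analysis([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlation_analysis([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestTypeIControl:
    def test_independent_cohort_rarely_reports_significance(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            table = sample_independent_metric_table(seed=seed)
            rep = icc_stiffness_analysis(table, alpha=0.05)
            if rep.pearson_verdict == "not_significant" and rep.spearman_verdict == "not_significant":
                hits += 1
        assert hits / n_rep >= 0.90


class TestValidationCompare:
    def test_identical_series(self):
        calc = np.linspace(10, 25, 10)
        df, rep = validation_compare(calc, calc)
        assert np.allclose(df["diff_percent"], 0.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_two_percent_noise_stays_under_six_percent(self):
        # measured = calculated (1 + eps), eps ~ N(0, 0.02): across seeds the
        # per-patient differences stay small and the correlation high
        calc = np.linspace(10.0, 25.0, 10)
        n_ok_diff = n_ok_r = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            meas = calc * (1 + rng.normal(0, 0.02, calc.size))
            df, rep = validation_compare(calc, meas)
            n_ok_diff += df["diff_percent"].max() < 6.0
            n_ok_r += rep.pearson_r > 0.9
        assert n_ok_diff >= 45
        assert n_ok_r == 50

    def test_zero_measured_pair_flagged(self):
        df, _ = validation_compare([10.0, 12.0, 14.0, 16.0], [10.0, 0.0, 14.0, 16.0])
        assert bool(df["flagged"].iloc[1])
        assert np.isnan(df["diff_percent"].iloc[1])

    def test_single_pair_gives_difference_but_no_correlation(self):
        df, rep = validation_compare([10.0], [11.0])
        assert df["diff_percent"].iloc[0] == pytest.approx(100.0 / 11.0)
        assert rep is None


class TestGridStudy:
    def test_identical_levels_give_zero_difference(self, head_geometry, waveforms):
        from cranioflow.coupling import CouplingConfig

        report = grid_independence(
            head_geometry,
            waveforms,
            CouplingConfig(n_cycles=1, steps_per_cycle=8),
            levels=("coarse", "coarse"),
        )
        assert report.successive_diff_percent[0] == pytest.approx(0.0, abs=1e-12)
        assert report.levels == ["coarse", "coarse"]

    def test_needs_two_levels(self, head_geometry, waveforms):
        with pytest.raises(ValueError):
            grid_independence(head_geometry, waveforms, levels=("coarse",))
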