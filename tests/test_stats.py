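"""The statistical battery: frozen toy oracles and calibration properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covpet import stats


class TestCompareTwo:
    def test_exact_mann_whitney_separated_triples(self):
        # all 3 of one group below all 3 of the other: U = 0 and the exact
        # two-sided p enumerates to 2/C(6,3) = 0.1
        res = stats.compare_two([1, 2, 3], [4, 5, 6], mode="mw")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.details["method"] == "exact"

    def test_identical_groups_near_one_p(self):
        res = stats.compare_two([1, 2, 3], [1, 2, 3], mode="mw")
        assert res.p > 0.9

    def test_constant_identical_groups_flagged(self):
        res = stats.compare_two([2, 2, 2], [2, 2, 2], mode="mw")
        assert res.p == 1.0
        assert any("degenerate" in f for f in res.flags)

    def test_auto_selects_t_for_clean_normal_samples(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.2, 1, 80)
        res = stats.compare_two(a, b, mode="auto")
        assert res.details["selected"] == "t"
        assert res.name == "two-sample t"

    def test_auto_falls_back_to_mw_for_skewed_samples(self, rng):
        a = rng.exponential(1.0, 80)
        b = rng.exponential(1.3, 80)
        res = stats.compare_two(a, b, mode="auto")
        assert res.details["selected"] == "mw"

    def test_exact_agrees_with_asymptotic_untied(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        from scipy.stats import mannwhitneyu
        exact = mannwhitneyu(a, b, method="exact").pvalue
        approx = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_two([1, 2], [3, 4, 5])


class TestPairedCompare:
    def test_hand_computed_t(self):
        res = stats.paired_compare([1, 2, 3], [2, 3, 5])
        assert res.statistic == pytest.approx(-4.0, abs=1e-12)
        assert res.details["df"] == 2

    def test_identical_pairs_degenerate(self):
        res = stats.paired_compare([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert any("degenerate" in f for f in res.flags)

    def test_sign_antisymmetry(self, rng):
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.5, 0.3, size=12)
        forward = stats.paired_compare(pre, post)
        backward = stats.paired_compare(post, pre)
        assert forward.statistic == pytest.approx(-backward.statistic)
        assert forward.p == pytest.approx(backward.p)


class TestCompareThree:
    TOY = ([1, 2], [3, 4], [5, 6])

    def test_kruskal_wallis_rank_arithmetic(self):
        res = stats.compare_three(self.TOY, mode="kw")
        assert res.statistic == pytest.approx(12 / 42 * 89.5 - 21, abs=1e-9)
        assert res.statistic == pytest.approx(4.571, abs=1e-3)
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_anova_sum_of_squares_arithmetic(self):
        res = stats.compare_three(self.TOY, mode="anova")
        assert res.statistic == pytest.approx(16.0, abs=1e-9)  # MSB 8 / MSW 0.5

    def test_identical_groups_zero_statistic(self):
        groups = ([1.0, 2.0, 3.0],) * 3
        assert stats.compare_three(groups, mode="kw").statistic == pytest.approx(0.0)
        assert stats.compare_three(groups, mode="anova").statistic == pytest.approx(0.0)

    def test_dunn_flags_only_extreme_pair_on_toy(self):
        posthoc = stats.compare_three(self.TOY, mode="kw").posthoc
        p_adj = dict(zip(posthoc["pair"], posthoc["p_adj"]))
        assert p_adj["0-2"] < p_adj["0-1"]
        assert (posthoc["p_adj"] <= 1).all()

    def test_bonferroni_adjustment_caps_at_one(self):
        posthoc = stats.compare_three(([1, 2, 3], [1.1, 2.1, 3.1], [1.2, 2.2, 3.2]),
                                      mode="anova").posthoc
        assert (posthoc["p_adj"] <= 1).all()
        np.testing.assert_allclose(posthoc["p_adj"],
                                   np.minimum(1.0, posthoc["p_raw"] * 3))


class TestChiSquare:
    @pytest.mark.parametrize("table,expected", [
        ([[28, 36], [24, 15]], 3.068),   # gender, patients vs validation-style
        ([[27, 22], [28, 36]], 1.432),   # gender, controls vs patients-style
        ([[28, 36], [15, 16]], 0.181),   # gender, two lymphoma subtypes
        ([[10, 20], [20, 10]], 6.667),   # expected counts all 15
    ])
    def test_no_continuity_correction_values(self, table, expected):
        res = stats.chi_square_2x2(table)
        assert res.statistic == pytest.approx(expected, abs=5e-4)
        assert res.details["df"] == 1

    def test_balanced_table_zero(self):
        assert stats.chi_square_2x2([[10, 10], [10, 10]]).statistic == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            stats.chi_square_2x2([[0, 0], [5, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            stats.chi_square_2x2([[1.5, 2], [3, 4]])


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        assert stats.correlate([1, 2, 3], [2, 4, 6], "pearson").statistic == \
            pytest.approx(1.0)

    def test_spearman_rank_difference_formula(self):
        # ranks of y = (2,1,4,3); sum d^2 = 4; rho = 1 - 6*4/(4*15) = 0.6
        res = stats.correlate([1, 2, 3, 4], [2, 1, 4, 3], "spearman")
        assert res.statistic == pytest.approx(0.6, abs=1e-12)

    def test_reversed_monotone_spearman(self):
        res = stats.correlate([1, 2, 3, 4, 5], [10, 8, 5, 3, 1], "spearman")
        assert res.statistic == pytest.approx(-1.0)


class TestSteiger:
    def test_equal_correlations_zero(self):
        res = stats.compare_dependent_correlations(0.5, 0.5, 0.3, 50)
        assert res.statistic == 0.0

    def test_antisymmetry(self):
        forward = stats.compare_dependent_correlations(0.6, 0.4, 0.7, 60)
        backward = stats.compare_dependent_correlations(0.4, 0.6, 0.7, 60)
        assert forward.statistic == pytest.approx(-backward.statistic, abs=1e-12)
        assert forward.p == pytest.approx(backward.p)

    def test_toy_triple_matches_independent_formula(self):
        # independent recomputation of the pooled-backed Fisher-z statistic
        r_xy, r_xz, r_yz, n = 0.6, 0.4, 0.7, 60
        rbar = 0.5
        psi = r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
        c = psi / (1 - rbar**2) ** 2
        expected = (np.arctanh(0.6) - np.arctanh(0.4)) * np.sqrt((n - 3) / (2 - 2 * c))
        res = stats.compare_dependent_correlations(r_xy, r_xz, r_yz, n)
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_dependent_correlations(1.0, 0.4, 0.3, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_dependent_correlations(0.5, 0.4, 0.3, 3)

    @given(st.floats(-0.8, 0.8), st.floats(-0.8, 0.8), st.floats(-0.5, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_property(self, r_xy, r_xz, r_yz):
        z1 = stats.steiger_z(r_xy, r_xz, r_yz, 40)
        z2 = stats.steiger_z(r_xz, r_xy, r_yz, 40)
        assert np.isfinite(z1)
        assert z1 == pytest.approx(-z2, abs=1e-10)


class TestTypeOneErrorCalibration:
    """Seeded null simulations: empirical size near the nominal 5%."""

    N_SIM = 10_000
    BAND = (0.035, 0.065)

    def test_two_sample_t_level(self):
        rng = np.random.default_rng(101)
        a = rng.normal(size=(self.N_SIM, 25))
        b = rng.normal(size=(self.N_SIM, 25))
        from scipy.stats import ttest_ind
        p = ttest_ind(a, b, axis=1).pvalue
        assert self.BAND[0] < (p < 0.05).mean() < self.BAND[1]

    def test_paired_t_level(self):
        rng = np.random.default_rng(102)
        pre = rng.normal(size=(self.N_SIM, 20))
        post = pre + rng.normal(size=(self.N_SIM, 20))
        from scipy.stats import ttest_rel
        p = ttest_rel(pre, post, axis=1).pvalue
        assert self.BAND[0] < (p < 0.05).mean() < self.BAND[1]

    def test_mann_whitney_level(self):
        rng = np.random.default_rng(103)
        rejections = 0
        n_sim = 2000  # per-call test, not vectorizable; fewer draws
        for _ in range(n_sim):
            res = stats.compare_two(rng.normal(size=30), rng.normal(size=30),
                                    mode="mw")
            rejections += res.p < 0.05
        assert 0.03 < rejections / n_sim < 0.07

    def test_steiger_level(self):
        rate = steiger_null_rejection_rate(seed=104, n_sim=self.N_SIM)
        assert self.BAND[0] < rate < self.BAND[1]


def steiger_null_rejection_rate(seed: int, n_sim: int, n: int = 60) -> float:
    """Monte-Carlo size of the Steiger test under a trivariate-normal null
    with equal dependent correlations (rho_xy = rho_xz = 0.4, rho_yz = 0.5)."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.5], [0.4, 0.5, 1.0]])
    chol = np.linalg.cholesky(cov)
    draws = rng.standard_normal((n_sim, n, 3)) @ chol.T
    centered = draws - draws.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    r = lambda i, j: (centered[..., i] * centered[..., j]).sum(axis=1) / (
        norms[..., i] * norms[..., j])
    z = stats.steiger_z(r(0, 1), r(0, 2), r(1, 2), n)
    return float((np.abs(z) > 1.959963984540054).mean())
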