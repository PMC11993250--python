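"""Welch t, one-way ANOVA, BCa bootstrap and lumen-region comparisons,
cross-checked against scipy and closed-form identities."""

import numpy as np
import pytest
from scipy import stats as sps

from heartscore import (
    LumenMeasurement,
    bca_bootstrap_ci,
    bca_mean_difference_ci,
    compare_region_widths,
    cohort_region_widths,
    one_way_anova,
    pooled_t_test,
    region_lumen_widths,
    welch_t_test,
)
from heartscore.classical import _bca_endpoints


class TestWelch:
    def test_hand_computed_example(self):
        # mx-my=-1, se^2 = 1/3 + 1/3, t = -1/sqrt(2/3), df = 4 (Satterthwaite)
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1 / np.sqrt(2 / 3), abs=1e-10)
        assert res.degrees_of_freedom == pytest.approx(4.0, abs=1e-10)
        ref = sps.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples_give_t_zero_p_one(self):
        x = [0.3, 0.8, 1.1, 0.5]
        res = welch_t_test(x, list(x))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_reduces_to_pooled_t_at_equal_variance_equal_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = x + 2.0  # identical sample variance, shifted mean
        welch = welch_t_test(x, y)
        pooled = pooled_t_test(x, y)
        assert welch.degrees_of_freedom == pytest.approx(18.0, abs=1e-9)
        assert welch.statistic == pytest.approx(pooled.statistic, abs=1e-12)

    def test_sign_antisymmetry_and_p_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(1, 2, size=9)
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_rejects_undersized_or_constant(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestAnova:
    def test_two_groups_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(0.5, 1.3, size=rng.integers(3, 12))
            res = one_way_anova([x, y])
            t = pooled_t_test(x, y)
            assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-10)
            assert res.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_three_group_hand_decomposition(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 8.0]]
        # grand mean = 4; SSB = 3*((2-4)^2 + (4-4)^2 + (6-4)^2) = 24
        # SSW = 2 + 8 + 6 = 16; F = (24/2)/(16/6) = 4.5
        res = one_way_anova(groups)
        assert res.f_statistic == pytest.approx(4.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        ref = sps.f_oneway(*groups)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_within_variance_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], [3.0]])


class TestBca:
    def test_endpoints_reduce_to_percentile_without_correction(self):
        assert _bca_endpoints(0.0, 0.0, 0.10) == pytest.approx((0.05, 0.95))

    def test_constant_sample_degenerates_with_flag(self):
        res = bca_bootstrap_ci([2.0] * 10, np.mean, n_boot=200, seed=0)
        assert res.degenerate
        assert res.lower == res.upper == 2.0

    def test_interval_brackets_the_mean_and_narrows_with_alpha(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(size=40)
        ci95 = bca_bootstrap_ci(x, np.mean, n_boot=2000, alpha=0.05, seed=4)
        ci80 = bca_bootstrap_ci(x, np.mean, n_boot=2000, alpha=0.20, seed=4)
        assert ci95.lower <= ci95.statistic <= ci95.upper
        assert ci80.lower >= ci95.lower and ci80.upper <= ci95.upper

    def test_agrees_with_scipy_bca_on_skewed_sample(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(size=50)
        ours = bca_bootstrap_ci(x, np.mean, n_boot=4000, seed=3)
        ref = sps.bootstrap(
            (x,), np.mean, n_resamples=4000, confidence_level=0.95,
            method="BCa", random_state=np.random.default_rng(3),
        ).confidence_interval
        width = ref.high - ref.low
        assert ours.lower == pytest.approx(ref.low, abs=0.1 * width)
        assert ours.upper == pytest.approx(ref.high, abs=0.1 * width)

    def test_bias_correction_sign_tracks_skew(self):
        # for a right-skewed statistic the observed mean sits above the
        # bootstrap median, pushing z0 positive
        rng = np.random.default_rng(21)
        x = rng.lognormal(size=60)
        res = bca_bootstrap_ci(x, np.mean, n_boot=3000, seed=5)
        assert not res.degenerate

    def test_two_sample_difference_interval(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5, 1, size=30)
        y = rng.normal(3, 1, size=25)
        ci = bca_mean_difference_ci(x, y, n_boot=3000, seed=2)
        assert ci.lower <= ci.statistic <= ci.upper
        assert ci.lower > 0  # clearly separated means

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bca_bootstrap_ci([1.0, 2.0], np.mean)


def _measurements(embryo, diams, genotype="wt"):
    return [
        LumenMeasurement(genotype, embryo, p, d)
        for p, d in zip(("A2", "A3", "A4", "A6", "A7"), diams)
    ]


class TestRegionWidths:
    def test_uniform_diameters(self):
        w = region_lumen_widths(_measurements("e1", [1.0] * 5))
        assert (w.posterior_aorta_width, w.heart_proper_width) == (1.0, 1.0)

    def test_region_means(self):
        w = region_lumen_widths(_measurements("e1", [0.6, 0.6, 0.78, 2.0, 2.4]))
        assert w.posterior_aorta_width == pytest.approx(0.66)
        assert w.heart_proper_width == pytest.approx(2.2)

    def test_scale_equivariance(self):
        diams = [0.5, 0.7, 0.6, 2.0, 2.2]
        w1 = region_lumen_widths(_measurements("e1", diams))
        w3 = region_lumen_widths(_measurements("e1", [3 * d for d in diams]))
        assert w3.posterior_aorta_width == pytest.approx(3 * w1.posterior_aorta_width)
        assert w3.heart_proper_width == pytest.approx(3 * w1.heart_proper_width)

    def test_replicates_averaged_per_position(self):
        ms = _measurements("e1", [1.0] * 5) + [LumenMeasurement("wt", "e1", "A2", 3.0)]
        w = region_lumen_widths(ms)
        assert w.posterior_aorta_width == pytest.approx((2.0 + 1.0 + 1.0) / 3)

    def test_missing_position_raises(self):
        ms = _measurements("e1", [1.0] * 5)[:4]
        with pytest.raises(ValueError, match="missing lumen positions"):
            region_lumen_widths(ms)


class TestCompareRegionWidths:
    def test_dilated_heart_proper_is_detected(self):
        rng = np.random.default_rng(17)
        ms = []
        for i in range(15):
            diams = list(rng.normal(0.66, 0.1, 3)) + list(rng.normal(2.18, 0.1, 2))
            ms.extend(_measurements(f"e{i}", diams))
        res = compare_region_widths(ms, "wt")
        assert res.statistic > 0
        assert res.p_value < 0.001

    def test_cohort_widths_one_per_embryo(self):
        ms = _measurements("e1", [1.0] * 5) + _measurements("e2", [2.0] * 5)
        assert len(cohort_region_widths(ms, "wt")) == 2

    def test_single_embryo_raises(self):
        with pytest.raises(ValueError, match=">= 2 complete embryos"):
            compare_region_widths(_measurements("e1", [1.0] * 5), "wt")
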