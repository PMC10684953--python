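import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrlink.estimators import (InsufficientInstrumentsError, egger, ivw,
                               ivw_regression, mode_estimator, wald_ratio,
                               weighted_median)
from mrlink.harmonize import HarmonizedSet
from tests.conftest import harmonized_from_ratios


class TestWaldRatio:
    def test_delta_method_hand_calculation(self):
        e = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert e.beta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.05)

    def test_null_numerator(self):
        e = wald_ratio(0.1, 0.01, 0.0, 0.005)
        assert e.beta == 0.0 and e.pval == pytest.approx(1.0)

    def test_sign_flips_with_denominator(self):
        assert wald_ratio(-0.1, 0.01, 0.02, 0.005).beta == pytest.approx(-0.2)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.02, 0.005)

    def test_second_order_term_increases_se(self):
        first = wald_ratio(0.1, 0.02, 0.02, 0.005)
        second = wald_ratio(0.1, 0.02, 0.02, 0.005, second_order=True)
        assert second.se > first.se
        expected = np.sqrt(0.005**2 / 0.1**2 + 0.02**2 * 0.02**2 / 0.1**4)
        assert second.se == pytest.approx(expected)


class TestIVW:
    def test_weighted_mean_hand_calculation(self):
        h = harmonized_from_ratios([0.2, 0.4], [0.0025, 0.01])
        e = ivw(h, "fixed")
        assert e.beta == pytest.approx(0.24)
        assert e.se == pytest.approx(0.04472, abs=1e-5)

    def test_homogeneous_ratios_fixed_equals_mre(self):
        h = harmonized_from_ratios([0.3, 0.3, 0.3], [0.01, 0.02, 0.04])
        fe, mre = ivw(h, "fixed"), ivw(h, "mre")
        assert fe.beta == pytest.approx(0.3)
        assert mre.beta == pytest.approx(0.3)
        assert fe.se == pytest.approx(mre.se)

    @pytest.mark.parametrize("seed", range(20))
    def test_dual_route_agreement(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 40))
        h = HarmonizedSet.from_arrays(
            beta_x=rng.normal(0.1, 0.05, k) + 0.05,
            se_x=rng.uniform(0.005, 0.02, k),
            beta_y=rng.normal(0, 0.05, k),
            se_y=rng.uniform(0.005, 0.05, k))
        beta_w = ivw(h, "fixed").beta
        beta_r, se_r = ivw_regression(h)
        assert beta_r == pytest.approx(beta_w, abs=1e-10)
        assert se_r == pytest.approx(ivw(h, "fixed").se, abs=1e-10)

    def test_fixed_se_never_exceeds_mre_se(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(2, 30))
            h = harmonized_from_ratios(rng.normal(0.2, 0.3, k),
                                       rng.uniform(0.001, 0.05, k))
            assert ivw(h, "fixed").se <= ivw(h, "mre").se + 1e-15

    def test_single_instrument_rejected(self):
        h = harmonized_from_ratios([0.2], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_perfect_fit_exact(self):
        h = HarmonizedSet.from_arrays(
            beta_x=np.array([1.0, 2.0, 3.0]), se_x=np.full(3, 0.01),
            beta_y=np.array([0.3, 0.5, 0.7]), se_y=np.full(3, 0.1))
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.2, abs=1e-12)
        assert intercept.beta == pytest.approx(0.1, abs=1e-12)

    def test_proportional_data_zero_intercept(self):
        h = HarmonizedSet.from_arrays(
            beta_x=np.array([0.5, 1.0, 2.0, 4.0]), se_x=np.full(4, 0.01),
            beta_y=0.37 * np.array([0.5, 1.0, 2.0, 4.0]), se_y=np.full(4, 0.1))
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.37, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0.1, 0.05, 10)
        h1 = HarmonizedSet.from_arrays(
            beta_x=bx, se_x=np.full(10, 0.01),
            beta_y=0.2 * bx + rng.normal(0, 0.02, 10), se_y=np.full(10, 0.02))
        flip = rng.random(10) < 0.5
        h2 = HarmonizedSet.from_arrays(
            beta_x=np.where(flip, -h1.beta_x, h1.beta_x), se_x=h1.se_x,
            beta_y=np.where(flip, -h1.beta_y, h1.beta_y), se_y=h1.se_y)
        s1, i1 = egger(h1)
        s2, i2 = egger(h2)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        k = 25
        bx = np.abs(rng.normal(0.1, 0.05, k)) + 0.02
        by = 0.15 + 0.3 * bx + rng.normal(0, 0.05, k)
        sy = rng.uniform(0.02, 0.08, k)
        h = HarmonizedSet.from_arrays(beta_x=bx, se_x=np.full(k, 0.01),
                                      beta_y=by, se_y=sy)
        slope, intercept = egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_too_few_instruments(self):
        h = harmonized_from_ratios([0.1, 0.2], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_plain_median_under_equal_weights(self):
        h = harmonized_from_ratios([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_hand_interpolated_value(self):
        # weights {1, 1, 4}: s = {0.0833, 0.25, 0.6667} -> interp at 0.5 = 0.26
        h = harmonized_from_ratios([0.1, 0.2, 0.3], [1.0, 1.0, 0.25])
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.26)

    def test_bootstrap_deterministic_under_seed(self):
        h = harmonized_from_ratios([0.1, 0.25, 0.3, 0.18], [0.01] * 4)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se


class TestModes:
    def test_degenerate_distribution(self):
        h = harmonized_from_ratios([0.25] * 4, [0.01] * 4)
        for variant in ("simple", "weighted"):
            e = mode_estimator(h, variant, n_boot=20, seed=0)
            assert e.beta == pytest.approx(0.25)

    def test_mode_resists_outlier_unlike_mean(self):
        h = harmonized_from_ratios([0.2, 0.2, 0.2, 0.9], [0.01] * 4)
        e = mode_estimator(h, "simple", n_boot=20, seed=0)
        assert abs(e.beta - 0.2) < 0.05
        assert abs(e.beta - 0.375) > 0.1

    def test_downweighted_outlier_pulls_weighted_mode_toward_bulk(self):
        ratios = [0.2, 0.25, 0.3, 0.6]
        weighted = mode_estimator(
            harmonized_from_ratios(ratios, [0.01, 0.01, 0.01, 1.0]),
            "weighted", n_boot=20, seed=0)
        simple = mode_estimator(
            harmonized_from_ratios(ratios, [0.01, 0.01, 0.01, 1.0]),
            "simple", n_boot=20, seed=0)
        assert abs(weighted.beta - 0.2) <= abs(simple.beta - 0.2) + 1e-9


class TestSharedInvariants:
    def _panel(self, h, fast=True):
        nb = 30
        slope, _ = egger(h)
        return [ivw(h, "fixed"), ivw(h, "mre"), slope,
                weighted_median(h, n_boot=nb, seed=1),
                mode_estimator(h, "weighted", n_boot=nb, seed=1),
                mode_estimator(h, "simple", n_boot=nb, seed=1)]

    def test_all_estimators_return_c_on_constant_ratios(self):
        c = 0.42
        bx = np.array([0.05, 0.08, 0.11, 0.14, 0.17, 0.2])
        h = HarmonizedSet.from_arrays(
            beta_x=bx, se_x=np.full(6, 0.005),
            beta_y=c * bx, se_y=np.full(6, 0.01))
        for e in self._panel(h):
            assert e.beta == pytest.approx(c, abs=1e-9), e.method

    @pytest.mark.parametrize("lam", [2.0, -1.5])
    def test_scale_equivariance(self, lam):
        rng = np.random.default_rng(7)
        k = 12
        bx = np.abs(rng.normal(0.1, 0.03, k)) + 0.02
        by = 0.2 * bx + rng.normal(0, 0.03, k)
        sy = rng.uniform(0.01, 0.05, k)
        h1 = HarmonizedSet.from_arrays(beta_x=bx, se_x=np.full(k, 0.005),
                                       beta_y=by, se_y=sy)
        h2 = HarmonizedSet.from_arrays(beta_x=bx, se_x=np.full(k, 0.005),
                                       beta_y=lam * by, se_y=abs(lam) * sy)
        for e1, e2 in zip(self._panel(h1), self._panel(h2)):
            assert e2.beta == pytest.approx(lam * e1.beta, abs=1e-6), e1.method
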