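import math

import numpy as np
import pytest
from scipy import stats

from flyburst.effects import (
    BootstrapEffectSize,
    EffectSizeRegression,
    bootstrap_mean_difference,
    child_seed,
    cohens_d,
    cumulative_seizing_fraction,
    fit_effect_size_regression,
    percent_change,
)
from flyburst.errors import DegenerateDesignError, ValidationError


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_example_pooled_sd(self):
        # sample variances are 2 and 2, pooled SD sqrt(2)
        assert cohens_d([0, 2], [1, 3]) == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(ValidationError):
            cohens_d([1, 1, 1], [2, 2, 2])

    def test_shift_and_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 25)
        d = cohens_d(a, b)
        assert cohens_d(a + 7, b + 7) == pytest.approx(d)
        assert cohens_d(a * 3, b * 3) == pytest.approx(d)

    def test_swap_negates(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 25)
        assert cohens_d(b, a) == pytest.approx(-cohens_d(a, b))


class TestBootstrapMeanDifference:
    def test_identical_groups_ci_contains_zero(self):
        eff = bootstrap_mean_difference([1, 2, 3], [1, 2, 3], n_boot=1000, seed=0)
        assert eff.mean_difference == 0.0
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_zero_variance_degenerate_interval(self):
        eff = bootstrap_mean_difference([0, 0, 0, 0], [1, 1, 1, 1], n_boot=1000, seed=0)
        assert eff.mean_difference == 1.0
        assert (eff.ci_low, eff.ci_high) == (1.0, 1.0)
        assert math.isnan(eff.cohens_d)  # pooled SD is zero here

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        e1 = bootstrap_mean_difference(a, b, n_boot=2000, seed=42)
        e2 = bootstrap_mean_difference(a, b, n_boot=2000, seed=42)
        assert e1 == e2
        e3 = bootstrap_mean_difference(a, b, n_boot=2000, seed=43)
        assert e3.ci_low != e1.ci_low

    def test_swap_mirrors_interval(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(1, 1, 30)
        fwd = bootstrap_mean_difference(a, b, n_boot=5000, seed=1)
        rev = bootstrap_mean_difference(b, a, n_boot=5000, seed=1)
        assert rev.mean_difference == pytest.approx(-fwd.mean_difference)
        assert rev.cohens_d == pytest.approx(-fwd.cohens_d)
        # mirrored CI up to bootstrap Monte Carlo error
        assert rev.ci_low == pytest.approx(-fwd.ci_high, abs=0.1)
        assert rev.ci_high == pytest.approx(-fwd.ci_low, abs=0.1)

    def test_matches_scipy_bca_interval(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)
        eff = bootstrap_mean_difference(a, b, n_boot=20000, seed=5)
        ref = stats.bootstrap(
            (b, a),
            lambda y, x, axis: np.mean(y, axis=axis) - np.mean(x, axis=axis),
            n_resamples=20000,
            method="BCa",
            random_state=np.random.default_rng(99),
        )
        assert eff.ci_method == "bca"
        assert eff.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert eff.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_mean_difference([1.0], [1, 2, 3], n_boot=1000)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_mean_difference([1, np.nan, 3], [1, 2, 3], n_boot=1000)

    def test_estimator_wrapper_exposes_fitted_attributes(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        est = BootstrapEffectSize(n_boot=1000, random_state=3).fit(a, b)
        assert est.mean_difference_ == est.effect_.mean_difference
        assert est.ci_low_ <= est.mean_difference_ <= est.ci_high_

    def test_child_seed_stable_across_label_sets(self):
        s1 = child_seed(7, "ctrl", "bss", "eshock").generate_state(4)
        s2 = child_seed(7, "ctrl", "bss", "eshock").generate_state(4)
        s3 = child_seed(7, "ctrl", "eas", "eshock").generate_state(4)
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, s3)


class TestRegression:
    def test_collinear_points_r2_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = fit_effect_size_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_forced_perfect_fit(self):
        res = fit_effect_size_regression([0.0, 1.0], [5.0, 2.0])
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_decoupled_y_near_zero(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.permutation(x)
        assert fit_effect_size_regression(x, y).r_squared < 0.1

    def test_affine_invariance_of_r2(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        base = fit_effect_size_regression(x, y).r_squared
        trans = fit_effect_size_regression(3 * x - 2, -0.5 * y + 4).r_squared
        assert trans == pytest.approx(base, rel=1e-9)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_effect_size_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bootstrap_r2_ci_brackets_estimate(self, rng):
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0, 0.5, 12)
        res = fit_effect_size_regression(x, y, n_boot=1000, seed=0)
        assert res.r2_ci_low <= res.r2_ci_high
        assert 0.0 <= res.r2_ci_low and res.r2_ci_high <= 1.0

    def test_estimator_predict(self):
        est = EffectSizeRegression().fit([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        np.testing.assert_allclose(est.predict([3.0]), [7.0])


class TestPercentChange:
    def test_equal_means_zero(self):
        assert percent_change([5, 5], [5, 5]) == 0.0

    def test_ratio_arithmetic(self):
        # control mean 100, treated mean 344.11 -> +244.11%
        assert percent_change([344.11], [100.0]) == pytest.approx(244.11)

    def test_reduction_is_negative(self):
        assert percent_change([50.0], [100.0]) == pytest.approx(-50.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValidationError):
            percent_change([1.0], [0.0, 0.0])


class TestCumulativeSeizing:
    CHECKPOINTS = np.arange(10, 121, 10)

    def test_hand_counted_curve(self):
        onsets = [10.0, 30.0, 50.0, None]  # 4 animals, one censored
        curve = cumulative_seizing_fraction(onsets, self.CHECKPOINTS)
        expected = [0.25, 0.25, 0.5, 0.5] + [0.75] * 8
        np.testing.assert_allclose(curve, expected)

    def test_all_onsets_zero_is_constant_one(self):
        curve = cumulative_seizing_fraction([0.0, 0.0], self.CHECKPOINTS)
        np.testing.assert_array_equal(curve, np.ones_like(self.CHECKPOINTS, dtype=float))

    def test_all_censored_is_constant_zero(self):
        curve = cumulative_seizing_fraction([None, None], self.CHECKPOINTS)
        np.testing.assert_array_equal(curve, np.zeros_like(self.CHECKPOINTS, dtype=float))

    def test_t_max_censors_late_onsets(self):
        curve = cumulative_seizing_fraction([10.0, 130.0], self.CHECKPOINTS, t_max=120.0)
        assert curve[-1] == pytest.approx(0.5)

    def test_non_decreasing(self, rng):
        onsets = list(rng.uniform(0, 150, 30)) + [None] * 5
        curve = cumulative_seizing_fraction(onsets, self.CHECKPOINTS, t_max=120.0)
        assert np.all(np.diff(curve) >= 0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_seizing_fraction([], self.CHECKPOINTS)
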