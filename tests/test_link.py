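"""Arousal-performance link: standardization, robust fit, indices."""

import numpy as np
import pytest
from scipy import stats

from cogstate.link import (fit_inverted_u, high_state_index, point_biserial,
                           standardize, trial_average_arousal)
from cogstate.trajectory import StateTrajectory


def _traj(means, variances):
    k = len(means)
    return StateTrajectory(np.zeros(k), np.ones(k), np.asarray(means),
                           np.asarray(variances), np.asarray(means),
                           np.asarray(variances), np.full(k, 0.5),
                           np.zeros(k - 1), np.zeros(k - 1))


class TestStandardize:
    def test_hand_computed_example(self):
        out = standardize([1, 2, 3])
        assert out == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_idempotent_on_standardized_input(self):
        v = standardize(np.random.default_rng(0).normal(3, 2, 50))
        assert np.allclose(standardize(v), v, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            standardize([5.0, 5.0])


class TestTrialAverage:
    def test_aligned_bins_identity(self):
        traj = _traj([1.0, 2.0, 3.0], [0.1] * 3)
        windows = np.array([[0, 2], [2, 4], [4, 6.0]])
        out = trial_average_arousal(traj, windows, bin_width=2.0)
        assert np.allclose(out, [1, 2, 3])

    def test_two_bins_per_trial_averaged(self):
        traj = _traj([1.0, 3.0], [0.1] * 2)
        out = trial_average_arousal(traj, np.array([[0, 2.0]]), bin_width=1.0)
        assert out[0] == pytest.approx(2.0)

    def test_matches_brute_force_windowed_mean(self, rng):
        k = 50
        traj = _traj(rng.normal(0, 1, k), np.full(k, 0.1))
        bin_width = 0.7
        windows = np.array([[i * 3.5, i * 3.5 + 3.5] for i in range(9)])
        out = trial_average_arousal(traj, windows, bin_width=bin_width)
        centers = (np.arange(k) + 0.5) * bin_width
        for i, (s, e) in enumerate(windows):
            mask = (centers >= s) & (centers < e)
            assert out[i] == pytest.approx(traj.x_smooth[mask].mean())

    def test_uncovered_trial_raises_with_indices(self):
        traj = _traj([1.0], [0.1])
        with pytest.raises(ValueError, match="not covered"):
            trial_average_arousal(traj, np.array([[100.0, 102.0]]),
                                  bin_width=2.0)


class TestInvertedU:
    def test_clean_quadratic_reproduced_exactly(self):
        x = standardize([-1.0, -0.5, 0.0, 0.5, 1.0])
        y = -x ** 2
        fit = fit_inverted_u(x, y - y.mean())
        assert fit.lambda1 < 0
        assert np.all(fit.weights == 1.0)
        pred = fit.lambda1 * x ** 2 + fit.lambda2 * x + fit.lambda3
        assert np.allclose(pred, y - y.mean(), atol=1e-10)

    def test_gross_outlier_downweighted(self, rng):
        n = 80
        x = standardize(rng.normal(0, 1, n))
        y = -0.8 * x ** 2 + 0.2 * x + rng.normal(0, 0.1, n)
        y_out = y.copy()
        y_out[7] += 25.0
        fit = fit_inverted_u(x, y_out)
        # OLS oracle on the clean data
        beta_ols, *_ = np.linalg.lstsq(
            np.column_stack([x ** 2, x, np.ones(n)]), y, rcond=None)
        assert fit.weights[7] < 0.05
        assert fit.lambda1 == pytest.approx(beta_ols[0], rel=0.05)
        assert fit.lambda2 == pytest.approx(beta_ols[1], rel=0.08, abs=0.02)

    def test_agrees_with_statsmodels_rlm(self, rng):
        """Independent IRLS oracle: statsmodels RLM with Tukey biweight."""
        import statsmodels.api as sm
        n = 150
        x = standardize(rng.normal(0, 1, n))
        y = -0.6 * x ** 2 + 0.1 * x + 0.3 + rng.normal(0, 0.3, n)
        y[3] += 8.0
        fit = fit_inverted_u(x, y)
        design = sm.add_constant(np.column_stack([x ** 2, x]))
        rlm = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(4.685)).fit(
            scale_est="mad")
        assert fit.lambda1 == pytest.approx(rlm.params[1], abs=0.02)
        assert fit.lambda2 == pytest.approx(rlm.params[2], abs=0.02)
        assert fit.lambda3 == pytest.approx(rlm.params[0], abs=0.02)

    def test_type_one_error_rate_near_nominal(self):
        """Under the null (y independent of x) the quadratic term is
        rejected at 5% in at most ~10% of replicates."""
        rejections = 0
        n_rep = 120
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = standardize(rng.normal(0, 1, 300))
            y = standardize(rng.normal(0, 1, 300))
            fit = fit_inverted_u(x, y)
            rejections += fit.pvalues[0] < 0.05
        assert rejections / n_rep <= 0.10

    def test_matches_ols_on_clean_gaussian_data(self, rng):
        n = 200
        x = standardize(rng.normal(0, 1, n))
        y = -0.5 * x ** 2 + 0.2 * x + rng.normal(0, 0.2, n)
        fit = fit_inverted_u(x, y)
        beta, *_ = np.linalg.lstsq(np.column_stack([x ** 2, x, np.ones(n)]),
                                   y, rcond=None)
        assert fit.lambda1 == pytest.approx(beta[0], rel=0.01, abs=0.01)
        assert fit.lambda2 == pytest.approx(beta[1], rel=0.01, abs=0.01)
        assert fit.lambda3 == pytest.approx(beta[2], rel=0.01, abs=0.01)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_inverted_u(np.zeros(10), np.arange(10.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_inverted_u(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1, 2]))


class TestPointBiserial:
    def test_hand_checkable_example(self):
        g = np.array([0, 0, 0, 1, 1, 1])
        v = np.array([1.0, 2, 3, 2, 3, 4])
        assert point_biserial(g, v) == pytest.approx(0.5222, abs=1e-3)

    def test_equals_scipy_pointbiserialr(self, rng):
        g = (rng.random(60) < 0.4).astype(int)
        v = rng.normal(0, 1, 60) + 0.5 * g
        ours = point_biserial(g, v)
        ref = stats.pointbiserialr(g, v).correlation
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_identical_group_means_give_zero(self):
        g = np.array([0, 0, 1, 1])
        v = np.array([1.0, 3.0, 1.0, 3.0])
        assert point_biserial(g, v) == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        g = (rng.random(40) < 0.5).astype(int)
        v = rng.normal(2, 3, 40) + g
        base = point_biserial(g, v)
        assert point_biserial(g, 5 * v - 7) == pytest.approx(base, abs=1e-12)
        assert point_biserial(1 - g, v) == pytest.approx(-base, abs=1e-12)

    def test_bounded_by_one_for_separated_groups(self):
        g = np.array([0, 0, 1, 1])
        v = np.array([0.0, 1e-9, 10.0, 10.0 + 1e-9])
        assert abs(point_biserial(g, v)) <= 1.0 + 1e-12

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            point_biserial(np.ones(5, int), np.arange(5.0))


class TestHighStateIndex:
    def test_state_at_threshold_gives_half(self):
        traj = _traj([1.0, 1.0], [0.25, 0.25])
        hai = high_state_index(traj, threshold=1.0)
        assert np.allclose(hai, 0.5)

    def test_gaussian_quantile(self):
        traj = _traj([1.96], [1.0])
        hai = high_state_index(traj, threshold=0.0)
        assert hai[0] == pytest.approx(0.975, abs=1e-3)

    def test_matches_monte_carlo_sampling(self, rng):
        means = rng.normal(0, 1, 8)
        variances = rng.uniform(0.2, 1.5, 8)
        traj = _traj(means, variances)
        hai = high_state_index(traj, threshold=0.3)
        for i in range(8):
            draws = rng.normal(means[i], np.sqrt(variances[i]), 100_000)
            assert hai[i] == pytest.approx((draws > 0.3).mean(), abs=0.005)

    def test_median_threshold_centers_index(self, rng):
        means = rng.normal(0, 2, 101)
        traj = _traj(means, np.full(101, 0.5))
        hai = high_state_index(traj, threshold="median")
        assert np.median(hai) == pytest.approx(0.5, abs=0.05)

    def test_unknown_threshold_keyword_rejected(self):
        with pytest.raises(ValueError):
            high_state_index(_traj([0.0], [1.0]), threshold="mean")
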