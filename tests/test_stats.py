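"""Evaluation metrics and cohort statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from murimetry.errors import ConfigError
from murimetry.io import KeypointSet
from murimetry.stats import (correlate, keypoint_mse, match_by_iou,
                             objectness_accuracy, residualize,
                             variance_f_test)
from murimetry.synthetic import generate_cohort, growth_curve


def ks(coords):
    return KeypointSet(np.asarray(coords, dtype=float).reshape(12, 2))


class TestKeypointMse:
    def test_zero_when_equal(self, rng):
        a = ks(rng.uniform(0, 100, (12, 2)))
        assert keypoint_mse([a], [a]) == 0.0

    def test_single_offset_keypoint(self, rng):
        coords = rng.uniform(10, 90, (12, 2))
        a = ks(coords)
        shifted = coords.copy()
        shifted[0] += (0.1, 0.2)
        b = ks(shifted)
        assert keypoint_mse([a], [b]) == pytest.approx(0.05 / 12, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = ks(rng.uniform(0, 100, (12, 2)))
        b = ks(rng.uniform(0, 100, (12, 2)))
        assert keypoint_mse([a], [b]) == pytest.approx(
            keypoint_mse([b], [a]), rel=1e-15)

    def test_monte_carlo_expectation_two_sigma_squared(self):
        # per-coordinate gaussian noise of sd sigma -> E[MSE] = 2 sigma^2
        rng = np.random.default_rng(7)
        sigma = 0.7
        gt, noisy = [], []
        for _ in range(1000 // 12 + 1):
            c = rng.uniform(20, 200, (12, 2))
            gt.append(ks(c))
            noisy.append(ks(c + rng.normal(0, sigma, (12, 2))))
        mse = keypoint_mse(gt, noisy)
        assert mse == pytest.approx(2 * sigma ** 2, rel=0.10)

    def test_invisible_points_excluded(self):
        a = ks(np.full((12, 2), 10.0))
        shifted = np.full((12, 2), 10.0)
        shifted[3] += 100
        b = KeypointSet(shifted)
        b.visibility[3] = 0
        assert keypoint_mse([a], [b]) == 0.0

    def test_no_matches_is_an_error(self):
        with pytest.raises(ConfigError):
            keypoint_mse([], [])


class TestMatching:
    def test_greedy_iou_matching(self):
        gt = np.array([[0, 0, 10, 10], [20, 20, 30, 30]])
        pred = np.array([[21, 21, 31, 31], [1, 1, 11, 11]])
        assert sorted(match_by_iou(gt, pred)) == [(0, 1), (1, 0)]

    def test_low_overlap_not_matched(self):
        gt = np.array([[0, 0, 10, 10]])
        pred = np.array([[9, 9, 19, 19]])
        assert match_by_iou(gt, pred) == []


class TestObjectnessAccuracy:
    def test_all_correct(self):
        assert objectness_accuracy([1, 2, 1], [1, 2, 1]) == 1.0

    def test_none_correct(self):
        assert objectness_accuracy([1, 2], [2, 1]) == 0.0

    def test_three_of_four(self):
        assert objectness_accuracy([1, 1, 2, 2], [1, 1, 2, 1]) == 0.75


class TestCorrelate:
    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=30)
        res = correlate(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_affine_invariance_exact(self, rng):
        x = rng.normal(size=25)
        res = correlate(x, 2 * x + 3)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(3.0, abs=1e-9)

    def test_hand_oracle_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        # direct evaluation of the covariance formula
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        res = correlate(x, y)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.r2 == pytest.approx(r_oracle ** 2, abs=1e-12)
        assert res.n == 5

    def test_r2_is_r_squared(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = correlate(x, y)
        assert res.r2 == pytest.approx(res.r ** 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigError):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestResidualize:
    def test_constant_lengths_give_zero_residuals(self):
        df = generate_cohort(100, seed=1, noise_sd=0.0)
        for bone in ("tibia",):
            df[f"{bone}_L"] = np.where(df["sex"] == "M", 25.0, 24.0)
        resid = residualize(df, "tibia", "L")
        assert np.abs(resid).max() < 1e-8

    def test_residual_mean_zero_per_sex(self):
        df = generate_cohort(300, seed=2, noise_sd=0.4)
        resid = residualize(df, "femur", "R")
        for sex in ("M", "F"):
            assert abs(resid[(df["sex"] == sex).to_numpy()].mean()) < 1e-8

    def test_recovers_injected_noise_sd(self):
        df = generate_cohort(500, seed=3, noise_sd=0.5)
        resid = residualize(df, "tibia", "L")
        assert np.std(resid) == pytest.approx(0.5, rel=0.10)

    def test_penalized_fit_keeps_mean_zero(self):
        df = generate_cohort(200, seed=4, noise_sd=0.3)
        resid = residualize(df, "pelvis", "L", penalty=10.0)
        for sex in ("M", "F"):
            assert abs(resid[(df["sex"] == sex).to_numpy()].mean()) < 1e-8

    def test_small_stratum_error_names_sex(self):
        df = generate_cohort(100, seed=5)
        df = df[df["sex"] == "M"].reset_index(drop=True)
        with pytest.raises(ConfigError, match="sex=F"):
            residualize(df, "tibia", "L")

    def test_removes_age_trend(self):
        df = generate_cohort(400, seed=6, noise_sd=0.2)
        resid = residualize(df, "femur", "L")
        trend = growth_curve(df["age"], df["sex"], "femur")
        # residuals should be uncorrelated with the age trend
        assert abs(np.corrcoef(resid, trend)[0, 1]) < 0.1


class TestVarianceFTest:
    def test_identical_samples_give_F_one(self, rng):
        a = rng.normal(size=50)
        res = variance_f_test(a, a)
        assert res.F == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_doubled_scale_gives_quarter_F(self, rng):
        a = rng.normal(size=80)
        a = a - a.mean()
        res = variance_f_test(a, 2 * a)
        assert res.F == pytest.approx(0.25, abs=1e-12)
        assert res.df == (79, 79)

    @given(st.integers(0, 500))
    def test_reciprocal_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = rng.normal(size=17)
        assert variance_f_test(a, b).F * variance_f_test(b, a).F \
            == pytest.approx(1.0, rel=1e-12)

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.standard_normal(200)
            b = rng.standard_normal(200)
            if variance_f_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ConfigError):
            variance_f_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
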