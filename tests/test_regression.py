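import math

import numpy as np
import pandas as pd
import pytest

from lrrmeta.exceptions import (
    InsufficientDataError,
    InvalidValueError,
    RankDeficiencyError,
)
from lrrmeta.regression import (
    average_raw_slope,
    cooks_distance,
    fit_meta_regression,
    incremental_moderator_test,
    r2_analog,
    weighted_moderator_correlation,
)


class TestFitMetaRegression:
    def test_noiseless_line_recovered(self, rng):
        x = rng.uniform(0, 100, 30)
        y = 0.25 + 0.004 * x
        v = np.full(30, 1e-12)
        fit = fit_meta_regression(y, v, {"x": x})
        assert fit.intercept_lnr == pytest.approx(0.25, abs=1e-6)
        assert fit.slopes_lnr["x"] == pytest.approx(0.004, abs=1e-8)

    def test_constant_moderator_rejected(self):
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        v = np.full(5, 0.2)
        with pytest.raises(RankDeficiencyError, match="x"):
            fit_meta_regression(y, v, {"x": np.full(5, 3.0)})

    def test_duplicate_columns_rejected(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        v = np.full(10, 0.2)
        with pytest.raises(RankDeficiencyError, match="b"):
            fit_meta_regression(y, v, {"a": x, "b": 2 * x})

    def test_too_few_effects_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_meta_regression(
                np.array([0.1, 0.2, 0.3]),
                np.full(3, 0.2),
                {"x": np.array([1.0, 2.0, 3.0])},
            )

    def test_missing_moderator_rejected(self):
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        v = np.full(5, 0.2)
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        with pytest.raises(InvalidValueError, match="missing"):
            fit_meta_regression(y, v, {"x": x})

    def test_affine_rescaling_invariance(self, rng):
        k = 40
        x = rng.uniform(0, 50, k)
        v = rng.uniform(0.1, 0.5, k)
        y = 0.2 + 0.01 * x + rng.normal(0, np.sqrt(0.05 + v))
        f1 = fit_meta_regression(y, v, {"x": x})
        f2 = fit_meta_regression(y, v, {"x": 4.0 * x + 7.0})
        assert f2.slopes_lnr["x"] == pytest.approx(f1.slopes_lnr["x"] / 4.0)
        assert f2.p_value[1] == pytest.approx(f1.p_value[1], rel=1e-6)

    def test_reduces_to_ols_without_within_variance(self, rng):
        k = 25
        x = rng.uniform(-2, 2, k)
        y = 0.3 - 0.1 * x + rng.normal(0, 0.4, k)
        v = np.full(k, 1e-10)  # all variance is between-study
        fit = fit_meta_regression(y, v, {"x": x})
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        assert fit.intercept_lnr == pytest.approx(intercept_ols, abs=1e-4)
        assert fit.slopes_lnr["x"] == pytest.approx(slope_ols, abs=1e-4)

    def test_kh_p_uses_t_reference(self, rng):
        from scipy import stats

        k = 12
        x = rng.uniform(0, 10, k)
        v = rng.uniform(0.1, 0.4, k)
        y = rng.normal(0.3, np.sqrt(0.1 + v))
        fit = fit_meta_regression(y, v, {"x": x})
        expected = 2 * stats.t.sf(abs(fit.t_stat[1]), k - 2)
        assert fit.p_value[1] == pytest.approx(expected)

    def test_slope_recovery_under_generative_model(self, rng):
        # mean over replicates near the generating slope
        ests = []
        for _ in range(30):
            k = 200
            x = rng.lognormal(math.log(1.3), 0.4, k)
            v = np.full(k, 0.5)
            y = 0.3 + 0.05 * (x - x.mean()) + rng.normal(0, np.sqrt(0.02 + v))
            fit = fit_meta_regression(y, v, {"x": x})
            ests.append(fit.slopes_lnr["x"])
        assert np.mean(ests) == pytest.approx(0.05, abs=0.02)


class TestAverageRawSlope:
    @pytest.mark.parametrize(
        "intercept,slope,lo,hi,expected",
        [
            (-0.0149, 0.0079, 0, 100, 0.0119),
            (0.0842, 0.0035, 0, 100, 0.0046),
            (0.1472, 0.0022, 0, 100, 0.0029),
            (21.8340, -0.0107, 1980, 2014, -0.0171),
            (11.8610, -0.0058, 1980, 2014, -0.0077),
            (3.2287, -0.0015, 1980, 2014, -0.0019),
        ],
    )
    def test_published_back_transformations(self, intercept, slope, lo, hi, expected):
        assert round(average_raw_slope(intercept, slope, lo, hi), 4) == expected

    @pytest.mark.parametrize("intercept", [-3.0, 0.0, 2.5])
    def test_flat_fit_back_transforms_flat(self, intercept):
        assert average_raw_slope(intercept, 0.0, 0, 100) == pytest.approx(0.0)

    def test_sign_matches_lnr_slope(self, rng):
        for _ in range(20):
            intercept = rng.normal()
            slope = rng.normal() * 0.05
            lo, hi = sorted(rng.uniform(0, 100, 2))
            if hi - lo < 1e-6 or slope == 0:
                continue
            raw = average_raw_slope(intercept, slope, lo, hi)
            assert np.sign(raw) == np.sign(slope)

    def test_degenerate_range_rejected(self):
        with pytest.raises(InvalidValueError):
            average_raw_slope(0.1, 0.01, 50, 50)


class TestR2Analog:
    def test_all_explained(self):
        assert r2_analog(0.0, 0.2) == pytest.approx(100.0)

    def test_nothing_explained(self):
        assert r2_analog(0.2, 0.2) == pytest.approx(0.0)

    def test_undefined_when_total_zero(self):
        assert r2_analog(0.0, 0.0) is None

    def test_negative_raw_truncated_to_zero(self):
        assert r2_analog(0.3, 0.2) == 0.0

    def test_scale_invariance(self):
        assert r2_analog(0.05, 0.2) == pytest.approx(r2_analog(0.5, 2.0))

    def test_fit_reports_none_when_tau2_total_zero(self, rng):
        # homogeneous effects with big variances: tau2 estimates are 0
        k = 20
        x = rng.uniform(0, 10, k)
        y = np.full(k, 0.3)
        v = np.full(k, 1.0)
        fit = fit_meta_regression(y, v, {"x": x})
        assert fit.tau2_total == pytest.approx(0.0, abs=1e-10)
        assert fit.r2_analog is None


class TestIncrementalModeratorTest:
    def test_unknown_target_rejected(self, rng):
        y = rng.normal(size=12)
        v = np.full(12, 0.3)
        mods = {"a": rng.normal(size=12)}
        with pytest.raises(InvalidValueError, match="missing_mod"):
            incremental_moderator_test(y, v, mods, "missing_mod")

    def test_duplicated_target_rank_deficient(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        v = np.full(15, 0.3)
        with pytest.raises(RankDeficiencyError):
            incremental_moderator_test(y, v, {"a": x, "b": x.copy()}, "b")

    def test_strong_partial_slope_detected(self, rng):
        k = 120
        a = rng.normal(size=k)
        b = rng.normal(size=k)
        v = np.full(k, 0.1)
        y = 0.2 + 0.02 * a + 0.8 * b + rng.normal(0, np.sqrt(0.02 + v))
        p = incremental_moderator_test(y, v, {"a": a, "b": b}, "b")
        assert p < 0.001

    def test_null_target_moderate_p(self, rng):
        # scaled-down type-I check; the calibrated version runs in acceptance
        k = 80
        rejections = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(size=k)
            b = rng.normal(size=k)
            v = np.full(k, 0.2)
            y = 0.2 + 0.1 * a + rng.normal(0, np.sqrt(0.05 + v))
            p = incremental_moderator_test(y, v, {"a": a, "b": b}, "b")
            rejections += p < 0.05
        assert rejections / reps < 0.2


class TestCooksDistance:
    def test_exact_fit_all_zero(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 0.1 + 0.02 * x
        v = np.full(15, 1e-10)
        fit = fit_meta_regression(y, v, {"x": x})
        rep = cooks_distance(fit, y, v, {"x": x})
        assert np.all(rep.cooks_d < 1e-6)

    def test_planted_outlier_has_largest_d(self, rng):
        k = 30
        x = rng.uniform(0, 10, k)
        v = np.full(k, 0.05)
        y = 0.1 + 0.02 * x + rng.normal(0, 0.1, k)
        y[5] += 4.0  # far-outlying study
        fit = fit_meta_regression(y, v, {"x": x})
        rep = cooks_distance(fit, y, v, {"x": x}, study_ids=[f"S{i}" for i in range(k)])
        assert rep.study_ids[int(np.argmax(rep.cooks_d))] == "S5"
        assert rep.flagged[5]

    def test_threshold_default_four_over_k(self, rng):
        k = 25
        x = rng.uniform(0, 10, k)
        v = np.full(k, 0.1)
        y = rng.normal(0.2, 0.3, k)
        fit = fit_meta_regression(y, v, {"x": x})
        rep = cooks_distance(fit, y, v, {"x": x})
        assert rep.threshold == pytest.approx(4.0 / k)

    def test_removing_max_d_moves_slope_most(self, rng):
        # refit oracle: dropping the max-D study changes the slope more than
        # dropping a random other study
        wins = 0
        for _ in range(20):
            k = 25
            x = rng.uniform(0, 10, k)
            v = rng.uniform(0.05, 0.2, k)
            y = 0.1 + 0.03 * x + rng.normal(0, np.sqrt(0.05 + v))
            y[int(rng.integers(k))] += rng.choice([-3.0, 3.0])
            fit = fit_meta_regression(y, v, {"x": x})
            rep = cooks_distance(fit, y, v, {"x": x})
            i_max = int(np.argmax(rep.cooks_d))
            others = [i for i in range(k) if i != i_max]
            i_rand = int(rng.choice(others))

            def refit_slope(drop):
                keep = np.ones(k, bool)
                keep[drop] = False
                f = fit_meta_regression(y[keep], v[keep], {"x": x[keep]})
                return f.slopes_lnr["x"]

            base = fit.slopes_lnr["x"]
            if abs(refit_slope(i_max) - base) >= abs(refit_slope(i_rand) - base):
                wins += 1
        assert wins >= 15


class TestWeightedModeratorCorrelation:
    def test_diagonal_is_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        r, p, stars = weighted_moderator_correlation(df, np.ones(20))
        assert r.loc["a", "a"] == 1.0
        assert r.loc["b", "b"] == 1.0

    def test_independent_moderators_near_zero(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=1000), "b": rng.normal(size=1000)}
        )
        r, _, _ = weighted_moderator_correlation(df, np.ones(1000))
        assert abs(r.loc["a", "b"]) < 0.1

    def test_recovers_negative_correlation(self, rng):
        k = 500
        a = rng.normal(size=k)
        b = -0.3 * a + math.sqrt(1 - 0.3**2) * rng.normal(size=k)
        df = pd.DataFrame({"a": a, "b": b})
        r, p, stars = weighted_moderator_correlation(df, np.ones(k))
        assert r.loc["a", "b"] == pytest.approx(-0.3, abs=0.1)
        assert p.loc["a", "b"] < 0.001
        assert stars.loc["a", "b"] == "***"

    def test_pairwise_complete_and_sparse_cells(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        b[:8] = np.nan  # only 2 complete pairs
        df = pd.DataFrame({"a": a, "b": b})
        r, p, stars = weighted_moderator_correlation(df, np.ones(10))
        assert np.isnan(r.loc["a", "b"])
        assert stars.loc["a", "b"] == ""
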