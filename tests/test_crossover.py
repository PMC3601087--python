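import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmtraj.crossover import (
    ROISeries,
    cross_term_check,
    crossover_point,
    extract_roi_means,
    fit_roi_trend,
    summarize_crossovers,
    welch_beyond_crossover,
    TrendFit,
)

# Crossover points printed for the study's abstinence-linked regions
POSITIVE_ABSTINENCE_CROSSOVERS = [29.9, 26.4, 42.3, 32.8, 38.0, 44.9, 37.1, 33.3]
NEGATIVE_ABSTINENCE_CROSSOVERS = [27.6, 26.6, 18.5]


def _series(cd_values, ctrl_values, abstinence=None, years=None, age=None, cluster_id=1):
    n = len(cd_values)
    rng = np.random.default_rng(0)
    cov = pd.DataFrame({
        "age": age if age is not None else rng.uniform(20, 55, n),
        "abstinence_weeks": abstinence if abstinence is not None else rng.uniform(1, 102, n),
        "years_use": years if years is not None else rng.uniform(0.3, 24, n),
    })
    return ROISeries(cluster_id=cluster_id, cd_values=np.asarray(cd_values, float),
                     ctrl_values=np.asarray(ctrl_values, float), covariates=cov)


class TestExtractRoiMeans:
    @pytest.fixture()
    def labeled_maps(self, rng):
        shape = (8, 8, 8)
        labels = np.zeros(shape, dtype=int)
        labels[2, 2, 2] = 1
        labels[4, 4, 4] = 2
        labels[4, 4, 5] = 2
        cohort = pd.DataFrame({
            "subject": ["a", "b", "c"],
            "group": ["CD", "CD", "control"],
            "age": [30.0, 40.0, 35.0],
            "abstinence_weeks": [10.0, 50.0, np.nan],
            "years_use": [5.0, 8.0, np.nan],
        })
        return labels, cohort

    def test_constant_map(self, labeled_maps):
        labels, cohort = labeled_maps
        maps = [np.full((8, 8, 8), c) for c in (0.3, 0.5, 0.7)]
        s = extract_roi_means(maps, cohort, labels, 1)
        np.testing.assert_allclose(s.cd_values, [0.3, 0.5])
        np.testing.assert_allclose(s.ctrl_values, [0.7])

    def test_single_voxel_cluster(self, labeled_maps, rng):
        labels, cohort = labeled_maps
        maps = [rng.uniform(0, 1, (8, 8, 8)) for _ in range(3)]
        s = extract_roi_means(maps, cohort, labels, 1)
        assert s.cd_values[0] == maps[0][2, 2, 2]

    def test_two_voxel_mean(self, labeled_maps):
        labels, cohort = labeled_maps
        m = np.zeros((8, 8, 8))
        m[4, 4, 4], m[4, 4, 5] = 0.4, 0.6
        s = extract_roi_means([m, m, m], cohort, labels, 2)
        assert s.cd_values[0] == pytest.approx(0.5)

    def test_empty_cluster_rejected(self, labeled_maps):
        labels, cohort = labeled_maps
        with pytest.raises(ValueError, match="empty"):
            extract_roi_means([np.zeros((8, 8, 8))] * 3, cohort, labels, 9)


class TestFitRoiTrend:
    def test_noiseless_line(self):
        weeks = np.linspace(2, 100, 20)
        s = _series(0.4 + 0.005 * weeks, [0.5] * 10, abstinence=weeks)
        fit = fit_roi_trend(s, "abstinence_weeks")
        assert fit.slope == pytest.approx(0.005, abs=1e-10)
        assert fit.intercept == pytest.approx(0.4, abs=1e-9)

    def test_orthogonal_nuisance_leaves_slope_unchanged(self):
        n = 24
        weeks = np.linspace(2, 100, n)
        # bounded alternating errors keep all Huber weights at 1
        e = 0.004 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        y = 0.4 + 0.005 * weeks + e
        # orthogonalize age against [1, weeks]
        raw_age = np.linspace(20, 55, n) ** 1.3
        Q = np.column_stack([np.ones(n), weeks])
        age = raw_age - Q @ np.linalg.lstsq(Q, raw_age, rcond=None)[0]
        s = _series(y, [0.5] * 10, abstinence=weeks, age=age)
        plain = fit_roi_trend(s, "abstinence_weeks")
        adjusted = fit_roi_trend(s, "abstinence_weeks", nuisance=("age",))
        assert adjusted.slope == pytest.approx(plain.slope, abs=1e-6)

    def test_noisy_slope_recovery_within_three_se(self):
        rng = np.random.default_rng(5)
        weeks = rng.uniform(1, 102, 43)
        y = 0.45 + 0.002 * weeks + rng.normal(0, 0.01, 43)
        s = _series(y, [0.5] * 43, abstinence=weeks)
        fit = fit_roi_trend(s, "abstinence_weeks")
        assert abs(fit.slope - 0.002) < 3 * fit.slope_se

    def test_rank_deficiency_rejected(self):
        s = _series(np.arange(10.0), [0.5] * 5, age=np.full(10, 30.0))
        with pytest.raises(ValueError, match="rank|collinear|constant"):
            fit_roi_trend(s, "age")


class TestCrossoverPoint:
    def test_arithmetic(self):
        fit = TrendFit(slope=0.005, intercept=0.4, slope_se=0.0, slope_t=0.0,
                       df_resid=10, covariate="abstinence_weeks")
        res = crossover_point(fit, control_mean=0.5)
        assert res.crossover == pytest.approx(20.0)
        assert res.valid

    def test_zero_slope_invalid_not_error(self):
        fit = TrendFit(slope=0.0, intercept=0.4, slope_se=0.0, slope_t=0.0,
                       df_resid=10, covariate="abstinence_weeks")
        res = crossover_point(fit, control_mean=0.5)
        assert not res.valid
        assert np.isnan(res.crossover)

    @settings(deadline=None, derandomize=True)
    @given(slope=st.floats(0.001, 0.1), intercept=st.floats(-1, 1),
           control=st.floats(-1, 1))
    def test_intersection_identity(self, slope, intercept, control):
        fit = TrendFit(slope=slope, intercept=intercept, slope_se=0.0, slope_t=0.0,
                       df_resid=10, covariate="abstinence_weeks")
        res = crossover_point(fit, control)
        assert intercept + slope * res.crossover == pytest.approx(control, abs=1e-10)

    def test_unit_equivariance_weeks_to_days(self):
        rng = np.random.default_rng(3)
        weeks = rng.uniform(1, 102, 30)
        y = 0.45 + 0.002 * weeks + rng.normal(0, 0.005, 30)
        s_weeks = _series(y, [0.5] * 20, abstinence=weeks)
        s_days = _series(y, [0.5] * 20, abstinence=weeks * 7.0)
        f_w = fit_roi_trend(s_weeks, "abstinence_weeks")
        f_d = fit_roi_trend(s_days, "abstinence_weeks")
        assert f_d.slope == pytest.approx(f_w.slope / 7.0, rel=1e-6)
        x_w = crossover_point(f_w, 0.5).crossover
        x_d = crossover_point(f_d, 0.5).crossover
        assert x_d == pytest.approx(7.0 * x_w, rel=1e-6)

    def test_plausibility_window_flag(self):
        fit = TrendFit(slope=0.005, intercept=0.4, slope_se=0.0, slope_t=0.0,
                       df_resid=10, covariate="abstinence_weeks")
        res = crossover_point(fit, 0.5, plausible_window=(0.0, 10.0))
        assert res.valid and not res.in_window
        assert res.crossover == pytest.approx(20.0)


class TestSummarizeCrossovers:
    def test_positive_abstinence_regions(self):
        s = summarize_crossovers(POSITIVE_ABSTINENCE_CROSSOVERS)
        assert s["mean"] == pytest.approx(35.5875, abs=1e-10)
        assert s["sd"] == pytest.approx(6.2059, abs=1e-3)
        assert (s["min"], s["max"]) == (26.4, 44.9)

    def test_negative_abstinence_regions(self):
        s = summarize_crossovers(NEGATIVE_ABSTINENCE_CROSSOVERS)
        assert s["mean"] == pytest.approx(24.2333, abs=1e-3)
        assert s["sd"] == pytest.approx(4.9903, abs=1e-3)

    def test_single_value(self):
        s = summarize_crossovers([30.0])
        assert s["mean"] == 30.0 and s["sd"] is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_crossovers([])


class TestWelchBeyondCrossover:
    def test_identical_groups_give_zero(self):
        vals = np.linspace(0.4, 0.6, 12)
        s = _series(vals, vals, abstinence=np.full(12, 50.0))
        res = welch_beyond_crossover(s, crossover=10.0)
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(8)
        ctrl = rng.normal(0.5, 0.02, 43)
        beyond = rng.normal(0.56, 0.02, 15)  # +3 sd shift
        cd = np.concatenate([rng.normal(0.45, 0.02, 28), beyond])
        weeks = np.concatenate([rng.uniform(1, 30, 28), rng.uniform(40, 102, 15)])
        s = _series(cd, ctrl, abstinence=weeks)
        res = welch_beyond_crossover(s, crossover=35.0)
        assert res.testable and res.p < 0.05 and res.t > 0

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.5, 0.02, 20)
        b = rng.normal(0.55, 0.02, 20)
        weeks = np.full(20, 50.0)
        r1 = welch_beyond_crossover(_series(a, b, abstinence=weeks), 0.0)
        r2 = welch_beyond_crossover(_series(b, a, abstinence=weeks), 0.0)
        assert r1.t == pytest.approx(-r2.t)

    def test_strictly_beyond_convention_and_small_groups(self):
        s = _series([0.5, 0.6, 0.7], [0.5] * 10, abstinence=np.array([10.0, 20.0, 30.0]))
        res = welch_beyond_crossover(s, crossover=20.0)  # only 30.0 is beyond
        assert not res.testable and res.n_beyond == 1


class TestCrossTermCheck:
    def test_constant_covariate_not_testable(self):
        s = _series(np.arange(12.0), [0.5] * 6, years=np.full(12, 9.0))
        res = cross_term_check(s, "years_use", nuisance=())
        assert not res["testable"]

    def test_specificity_on_unrelated_covariate(self):
        rng = np.random.default_rng(14)
        weeks = rng.uniform(1, 102, 43)
        years = rng.uniform(0.3, 24, 43)
        age = rng.uniform(20, 55, 43)
        y = 0.45 + 0.002 * weeks + rng.normal(0, 0.005, 43)
        s = _series(y, [0.5] * 43, abstinence=weeks, years=years, age=age)
        res = cross_term_check(s, "years_use")
        assert res["testable"] and not res["significant"]

    def test_sensitivity_on_shared_covariate(self):
        rng = np.random.default_rng(15)
        weeks = rng.uniform(1, 102, 43)
        years = rng.uniform(0.3, 24, 43)
        y = 0.45 + 0.002 * weeks - 0.004 * years + rng.normal(0, 0.005, 43)
        s = _series(y, [0.5] * 43, abstinence=weeks, years=years)
        res = cross_term_check(s, "years_use")
        assert res["significant"] and res["slope"] < 0
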