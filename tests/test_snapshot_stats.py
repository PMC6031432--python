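"""Snapshot statistics: kernel curves, G_cv, checkpoint contrast, variability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizerkit.snapshot_stats import (
    AgeCurve,
    checkpoint_contrast,
    doubling_ratio,
    gcv_analysis,
    gcv_paired,
    gcv_vs_age,
    mean_size_vs_age,
    size_variability,
    var_size_vs_age,
    variance_decomposition,
)

from conftest import make_null_snapshot


def _snap(age, size, phase=None):
    df = pd.DataFrame({"cell_id": np.arange(len(age)), "age_h": age, "size_au": size})
    df["nucleus_au"] = df["size_au"]
    df["phase"] = phase if phase is not None else "G1"
    return df


class TestMeanCurve:
    def test_constant_data_gives_flat_curve_with_zero_width_ci(self):
        rng = np.random.default_rng(0)
        snap = _snap(rng.uniform(0, 10, 200), np.full(200, 100.0))
        c = mean_size_vs_age(snap, n_boot=50, grid=np.arange(1.0, 9.1, 0.5))
        np.testing.assert_allclose(c.estimate, 100.0, rtol=1e-9)
        np.testing.assert_allclose(c.ci_hi - c.ci_lo, 0.0, atol=1e-9)

    def test_exact_on_affine_data(self):
        # local-linear regression reproduces an affine trend exactly
        rng = np.random.default_rng(1)
        age = rng.uniform(0, 20, 400)
        snap = _snap(age, 10.0 + 5.0 * age)
        grid = np.arange(2.0, 18.1, 0.5)
        c = mean_size_vs_age(snap, bandwidth=1.0, n_boot=0, grid=grid)
        np.testing.assert_allclose(c.estimate, 10.0 + 5.0 * grid, rtol=1e-8)

    def test_matches_statsmodels_local_linear(self):
        statsmodels = pytest.importorskip("statsmodels.nonparametric.kernel_regression")
        rng = np.random.default_rng(2)
        age = rng.uniform(0, 12, 250)
        size = 100 + 20 * np.sin(age / 2) + rng.normal(0, 5, 250)
        snap = _snap(age, size)
        grid = np.arange(2.0, 10.1, 1.0)
        ours = mean_size_vs_age(snap, bandwidth=0.8, n_boot=0, grid=grid)
        kr = statsmodels.KernelReg(size, age, var_type="c", reg_type="ll", bw=[0.8])
        theirs, _ = kr.fit(grid)
        np.testing.assert_allclose(ours.estimate, theirs, rtol=1e-7)

    def test_too_few_cells_rejected(self):
        snap = _snap(np.linspace(0, 5, 20), np.full(20, 1.0))
        with pytest.raises(ValueError, match="50"):
            mean_size_vs_age(snap)

    def test_tiny_bandwidth_without_kernel_mass_rejected(self):
        snap = _snap(np.full(60, 1.0), np.full(60, 5.0))
        with pytest.raises(ValueError, match="kernel mass"):
            mean_size_vs_age(snap, bandwidth=1e-4, grid=np.array([0.0, 1.0, 3.0]))

    def test_row_order_invariance(self, sizer_run):
        snap = sizer_run.snapshot
        shuffled = snap.sample(frac=1.0, random_state=7).reset_index(drop=True)
        grid = np.arange(1.0, 18.1, 0.5)
        c1 = mean_size_vs_age(snap, n_boot=0, grid=grid)
        c2 = mean_size_vs_age(shuffled, n_boot=0, grid=grid)
        np.testing.assert_allclose(c1.estimate, c2.estimate, rtol=1e-9)

    def test_bootstrap_ci_coverage_near_nominal(self):
        # 90% percentile bootstrap covers the true affine mean curve at close
        # to nominal rate (local-linear is unbiased on an affine trend)
        reps, n = 200, 2000
        grid = np.array([5.0, 10.0, 15.0])
        hits = np.zeros(len(grid))
        truth = 100.0 + 5.0 * grid
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            age = rng.uniform(0, 20, n)
            size = 100.0 + 5.0 * age + rng.normal(0, 15.0, n)
            c = mean_size_vs_age(
                _snap(age, size), n_boot=200, ci_level=0.90, grid=grid, seed=i
            )
            hits += (c.ci_lo <= truth) & (truth <= c.ci_hi)
        coverage = hits / reps
        assert np.all(np.abs(coverage - 0.90) <= 0.05)


class TestVarianceCurve:
    def test_deterministic_size_gives_zero_variance(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(0, 20, 500)
        c = var_size_vs_age(
            _snap(age, 10 + 5 * age), n_boot=0, grid=np.arange(2.0, 18.1, 0.5)
        )
        np.testing.assert_allclose(c.estimate, 0.0, atol=1e-6)

    def test_two_cohort_population_variances(self):
        # cohorts: age 0 sizes {8,12}, age 1 sizes {11,11} -> Var 4 and 0
        age = np.r_[np.zeros(60), np.ones(60)]
        size = np.r_[np.tile([8.0, 12.0], 30), np.full(60, 11.0)]
        c = var_size_vs_age(
            _snap(age, size), bandwidth=0.02, n_boot=0, grid=np.array([0.0, 1.0]),
            min_n_eff=10,
        )
        assert c.estimate[0] == pytest.approx(4.0, rel=1e-9)
        assert c.estimate[1] == pytest.approx(0.0, abs=1e-9)

    def test_no_feedback_variance_never_decreases_significantly(self, timer_run):
        # with Cov(S, dS) = 0 the lagged variance difference is Var(dS) >= 0
        _, v, g = gcv_analysis(
            timer_run.snapshot, bandwidth=1.5, lag=2.5, n_boot=100, seed=0
        )
        df = g.to_frame()
        df = df[df["age_h"] + 2.5 <= 18.0]
        ok = df.dropna(subset=["gcv"])
        # no run of >= 4 consecutive points with the 50% band fully below zero
        h = ((ok["ci_hi"] < 0) & (ok["gcv"] < 0)).to_numpy()
        run = 0
        for v_ in h:
            run = run + 1 if v_ else 0
            assert run < 4


class TestGcv:
    def test_hand_worked_cohort_example(self):
        mean = AgeCurve(np.array([0.0, 1.0]), np.array([10.0, 11.0]),
                        np.full(2, np.nan), np.full(2, np.nan), np.full(2, 100.0),
                        "mean", 1.0)
        var = AgeCurve(np.array([0.0, 1.0]), np.array([4.0, 0.0]),
                       np.full(2, np.nan), np.full(2, np.nan), np.full(2, 100.0),
                       "variance", 1.0)
        g = gcv_vs_age(mean, var, lag=1.0)
        assert g.delta_var[0] == -4.0
        assert g.delta_mean[0] == 1.0
        assert g.gcv[0] == pytest.approx(-2.0)

    def test_zero_delta_var_maps_to_zero(self):
        mean = AgeCurve(np.array([0.0, 1.0]), np.array([10.0, 11.0]),
                        np.full(2, np.nan), np.full(2, np.nan), np.full(2, 100.0),
                        "mean", 1.0)
        var = AgeCurve(np.array([0.0, 1.0]), np.array([4.0, 4.0]),
                       np.full(2, np.nan), np.full(2, np.nan), np.full(2, 100.0),
                       "variance", 1.0)
        assert gcv_vs_age(mean, var, lag=1.0).gcv[0] == 0.0

    def test_suppressed_where_mean_not_increasing(self):
        mean = AgeCurve(np.array([0.0, 1.0]), np.array([11.0, 10.0]),
                        np.full(2, np.nan), np.full(2, np.nan), np.full(2, 100.0),
                        "mean", 1.0)
        var = AgeCurve(np.array([0.0, 1.0]), np.array([4.0, 2.0]),
                       np.full(2, np.nan), np.full(2, np.nan), np.full(2, 100.0),
                       "variance", 1.0)
        assert np.isnan(gcv_vs_age(mean, var, lag=1.0).gcv[0])

    def test_lag_and_grid_validation(self):
        mean = AgeCurve(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2), np.zeros(2),
                        np.full(2, 100.0), "mean", 1.0)
        var = AgeCurve(np.array([0.0, 2.0]), np.zeros(2), np.zeros(2), np.zeros(2),
                       np.full(2, 100.0), "variance", 1.0)
        with pytest.raises(ValueError, match="share a grid"):
            gcv_vs_age(mean, var, lag=1.0)
        with pytest.raises(ValueError, match="lag"):
            gcv_vs_age(mean, mean, lag=-1.0)

    def test_size_independent_growth_equals_increment_cv(self):
        # increments Normal(10, 2) independent of size: G_cv = 2/10
        rng = np.random.default_rng(5)
        s1 = rng.normal(100.0, 6.0, 200_000)
        s2 = s1 + rng.normal(10.0, 2.0, 200_000)
        assert gcv_paired(s1, s2) == pytest.approx(0.2, abs=0.01)

    def test_paired_requires_growth(self):
        with pytest.raises(ValueError, match="increase"):
            gcv_paired(np.array([2.0, 3.0]), np.array([1.0, 2.0]))


class TestVarianceDecomposition:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_identity_holds_for_arbitrary_paired_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 300))
        scale = 10.0 ** rng.uniform(-3, 4)
        s1 = rng.normal(rng.uniform(-5, 5), 1.0, n) * scale
        s2 = s1 * rng.uniform(0.2, 2.0) + rng.normal(0, 0.5, n) * scale
        d = variance_decomposition(s1, s2)
        tol = 1e-10 * max(d["var_s1"], d["var_s2"], 1e-30)
        assert abs(d["residual"]) <= tol

    def test_shrinking_variance_implies_negative_covariance(self):
        rng = np.random.default_rng(6)
        s1 = rng.normal(100, 20, 500)
        s2 = 0.5 * s1 + 55 + rng.normal(0, 1, 500)  # contraction toward the mean
        d = variance_decomposition(s1, s2)
        assert d["delta_var"] < 0
        assert d["cov_s1_ds"] < 0
        # algebraically: delta_var < 0 forces Cov < -Var(dS)/2
        assert d["cov_s1_ds"] < -d["var_ds"] / 2


class TestCheckpointContrast:
    def test_sizer_population_shows_significant_positive_contrast(self, sizer_run):
        res = checkpoint_contrast(sizer_run.snapshot)
        assert res.t_statistic > 0
        assert res.p_value < 0.01
        assert (res.mean_postg1 > res.mean_g1).all()

    def test_null_population_rarely_rejects(self):
        # phases independent of size: rejections at alpha = 0.01 stay rare
        rejections = sum(
            checkpoint_contrast(make_null_snapshot(800, seed)).p_value < 0.01
            for seed in range(100)
        )
        assert rejections <= 5

    def test_sizer_g1_curve_plateaus_but_timer_does_not(self, sizer_run, timer_run):
        assert checkpoint_contrast(sizer_run.snapshot).plateau_flag
        assert not checkpoint_contrast(timer_run.snapshot).plateau_flag

    def test_needs_both_phases(self):
        snap = make_null_snapshot(200, 0)
        snap["phase"] = "G1"
        with pytest.raises(ValueError, match="both"):
            checkpoint_contrast(snap)


class TestDoublingRatio:
    def test_constructed_two_fold_fixture(self):
        age = np.r_[np.full(50, 0.5), np.full(50, 20.0)]
        size = np.r_[np.full(50, 100.0), np.full(50, 200.0)]
        phase = np.r_[np.full(50, "G1"), np.full(50, "M")].astype(object)
        assert doubling_ratio(_snap(age, size, phase)) == pytest.approx(2.0)

    def test_steady_sizer_population_doubles(self, sizer_run):
        assert doubling_ratio(sizer_run.snapshot) == pytest.approx(2.0, abs=0.1)

    def test_empty_group_rejected(self):
        snap = _snap(np.full(10, 5.0), np.full(10, 1.0))
        with pytest.raises(ValueError, match="empty"):
            doubling_ratio(snap)


class TestSizeVariability:
    def test_hand_worked_example(self):
        assert size_variability([1, 2, 3, 4, 100]) == pytest.approx(1 / 3)

    def test_scale_invariance(self):
        x = np.array([3.0, 7.0, 9.0, 15.0, 40.0])
        assert size_variability(x * 17.3) == pytest.approx(size_variability(x))

    def test_errors(self):
        with pytest.raises(ValueError):
            size_variability([1.0])
        with pytest.raises(ValueError, match="median"):
            size_variability([-5.0, -1.0, 0.0])

    def test_disabling_feedback_raises_variability(self, feedback_run, timer_run):
        # hsp90-inhibition-like loss of growth feedback: variability rises
        v_fb = size_variability(feedback_run.snapshot["size_au"].to_numpy())
        v_no = size_variability(timer_run.snapshot["size_au"].to_numpy())
        assert v_no > v_fb
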