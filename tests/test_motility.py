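"""MSD, speed autocorrelation, FBM model and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacmotil import motility, synth
from bacmotil.motility import Thresholds
from bacmotil.trajectory import Trajectory

def ballistic_traj(speed=10.0, n=500, fps=500.0, angle_deg=0.0):
    t = np.arange(n) / fps
    a = np.deg2rad(angle_deg)
    return Trajectory(t, speed * t * np.cos(a), speed * t * np.sin(a))


def stationary_traj(n=300, fps=500.0):
    t = np.arange(n) / fps
    return Trajectory(t, np.zeros(n), np.zeros(n))


class TestMSD:
    def test_stationary_msd_is_zero(self):
        curve = motility.msd(stationary_traj(), max_lag=50)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_ballistic_closed_form(self):
        # x = v t with v = 10 µm/s: MSD(tau) = 100 tau^2 exactly
        curve = motility.msd(ballistic_traj(speed=10.0), max_lag=100)
        np.testing.assert_allclose(curve.msd[1:], 100.0 * curve.tau[1:] ** 2,
                                   rtol=1e-9)

    def test_single_origin_variant(self):
        tr = ballistic_traj(speed=10.0)
        a = motility.msd(tr, max_lag=50, time_averaged=False)
        np.testing.assert_allclose(a.msd[1:], 100.0 * a.tau[1:] ** 2, rtol=1e-9)

    def test_max_lag_validation(self):
        with pytest.raises(ValueError):
            motility.msd(stationary_traj(n=10), max_lag=10)

    def test_brownian_ensemble_matches_2dK(self):
        # 2D Brownian: MSD = 4 K tau; check the ensemble mean against truth
        K = 0.8
        params = synth.FBMParams(hurst=0.5, diffusion_scale=K, n_steps=500)
        paths = synth.gen_fbm_ensemble(params, 300, seed=21)
        k = 25
        emp = ((paths[:, k:, :] - paths[:, :-k, :]) ** 2).sum(axis=2).mean()
        assert emp == pytest.approx(4 * K * k * params.dt, rel=0.1)


class TestMSDPowerLawFit:
    def test_ballistic_alpha_2_K_v2_over_4(self):
        curve = motility.msd(ballistic_traj(speed=10.0), max_lag=100)
        fit = motility.fit_msd_power_law(curve)
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.K == pytest.approx(25.0, rel=1e-6)

    def test_brownian_recovery(self):
        K = 1.5
        params = synth.FBMParams(hurst=0.5, diffusion_scale=K, n_steps=1000)
        paths = synth.gen_fbm_ensemble(params, 400, seed=22)
        lags = np.arange(1, 120)
        msd_vals = np.array([((paths[:, k:, :] - paths[:, :-k, :]) ** 2)
                             .sum(axis=2).mean() for k in lags])
        curve = motility.MSDCurve(tau=np.r_[0.0, lags * params.dt],
                                  msd=np.r_[0.0, msd_vals])
        fit = motility.fit_msd_power_law(curve)
        assert fit.alpha == pytest.approx(1.0, abs=0.1)
        assert fit.K == pytest.approx(K, rel=0.1)

    def test_subdiffusive_exponent(self):
        params = synth.FBMParams(hurst=0.3, n_steps=1000)
        paths = synth.gen_fbm_ensemble(params, 500, seed=23)
        lags = np.arange(1, 250)
        msd_vals = np.array([((paths[:, k:, :] - paths[:, :-k, :]) ** 2)
                             .sum(axis=2).mean() for k in lags])
        curve = motility.MSDCurve(tau=np.r_[0.0, lags * params.dt],
                                  msd=np.r_[0.0, msd_vals])
        assert motility.fit_msd_power_law(curve).alpha == pytest.approx(0.6, abs=0.1)


class TestSpeedSeries:
    def test_ballistic_speed_constant(self):
        for n in (7, 25):
            sp = motility.mean_speed_series(ballistic_traj(speed=55.0), n)
            np.testing.assert_allclose(sp.speed, 55.0, rtol=1e-9)
            assert len(sp.v) == 500 - n

    def test_stationary_speed_zero(self):
        sp = motility.mean_speed_series(stationary_traj(), 25)
        np.testing.assert_array_equal(sp.speed, 0.0)

    def test_runner_median_speed_recovered(self):
        p = synth.SwimmerParams(speed=62.0, rot_diffusion=0.05)
        tr = synth.gen_run_trajectory(p, 2000, 1 / 500, seed=30)
        sp = motility.mean_speed_series(tr, 25)
        assert np.median(sp.speed) == pytest.approx(62.0, rel=0.05)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            motility.mean_speed_series(stationary_traj(n=10), 10)


class TestSpeedAutocorrelation:
    def test_lag_zero_is_exactly_one(self):
        tr = synth.gen_fbm_trajectory(synth.FBMParams(hurst=0.4, n_steps=500),
                                      seed=31)
        acf = motility.speed_autocorrelation(motility.mean_speed_series(tr, 7))
        assert acf.C[0] == 1.0

    def test_constant_velocity_fully_correlated(self):
        acf = motility.speed_autocorrelation(
            motility.mean_speed_series(ballistic_traj(speed=20.0), 7))
        np.testing.assert_allclose(acf.C, 1.0, rtol=1e-9)

    def test_n7_gives_eight_points_in_unit_interval(self):
        tr = synth.gen_fbm_trajectory(synth.FBMParams(hurst=0.4, n_steps=400),
                                      seed=32)
        acf = motility.speed_autocorrelation(motility.mean_speed_series(tr, 7))
        in_unit = acf.xi[acf.xi <= 1.0 + 1e-12]
        assert len(in_unit) == 8
        np.testing.assert_allclose(in_unit, np.arange(8) / 7)

    def test_zero_speeds_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            motility.speed_autocorrelation(
                motility.mean_speed_series(stationary_traj(), 7))


class TestFBMAutocorrelation:
    def test_closed_form_values(self):
        assert motility.fbm_autocorrelation(0.0, 1.3) == pytest.approx(1.0)
        assert motility.fbm_autocorrelation(1.0, 1.0) == pytest.approx(0.0)
        assert motility.fbm_autocorrelation(1.0, 2.0) == pytest.approx(1.0)

    @given(st.floats(min_value=0.05, max_value=2.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_c1_sign_tracks_alpha_c(self, alpha_c):
        # C1 = (2^a - 2)/2: negative iff a < 1, zero at a = 1
        c1 = motility.fbm_autocorrelation(1.0, alpha_c)
        assert c1 == pytest.approx((2 ** alpha_c - 2) / 2)
        assert np.sign(c1) == np.sign(alpha_c - 1) or abs(c1) < 1e-12

    def test_fit_recovers_exact_curve(self):
        xi = np.arange(8) / 7
        curve = motility.AutocorrCurve(xi=xi,
                                       C=motility.fbm_autocorrelation(xi, 1.98))
        fit = motility.fit_fbm_autocorr(curve)
        assert fit.alpha_c == pytest.approx(1.98, abs=1e-6)
        assert fit.C1 == pytest.approx(motility.fbm_autocorrelation(1.0, 1.98))

    def test_subdiffusive_fbm_has_negative_c1(self):
        tr = synth.gen_fbm_trajectory(
            synth.FBMParams(hurst=0.3, n_steps=3000), seed=33)
        acf = motility.speed_autocorrelation(motility.mean_speed_series(tr, 7))
        fit = motility.fit_fbm_autocorr(acf)
        assert fit.C1 < 0

    def test_runner_has_positive_c1_and_high_alpha_c(self):
        tr = synth.gen_run_trajectory(synth.SwimmerParams(speed=55.0),
                                      3000, 1 / 500, seed=34)
        acf = motility.speed_autocorrelation(motility.mean_speed_series(tr, 7))
        fit = motility.fit_fbm_autocorr(acf)
        assert fit.C1 > 0.45
        assert fit.alpha_c > 1.52


class TestReversals:
    def test_programmed_reversals_recovered(self):
        p = synth.SwimmerParams(speed=55.0, reversal_rate=0.5,
                                reversal_pause=0.15)
        for seed in (0, 1, 3):
            tr = synth.gen_run_trajectory(p, 3000, 1 / 500, seed=seed)
            truth = tr.meta["reversal_times"]
            det = motility.detect_reversals(tr)
            assert len(det) == len(truth)
            for td, tt in zip(det, truth):
                assert abs(td - tt) < 0.2

    def test_straight_runner_has_no_reversals(self):
        tr = synth.gen_run_trajectory(synth.SwimmerParams(speed=55.0),
                                      3000, 1 / 500, seed=35)
        assert motility.detect_reversals(tr) == []


class TestClassification:
    def test_label_rule_on_reported_feature_values(self):
        # a fast cell with near-perfect speed memory is running; weak
        # anti-correlated memory floats
        assert motility.decide_label(c1=0.98, alpha_c=1.98) == "running"
        assert motility.decide_label(c1=-0.1, alpha_c=0.8) == "floating"
        assert motility.decide_label(c1=0.98, alpha_c=1.98, n_reversals=2) == "rwr"
        assert motility.decide_label(c1=0.5, alpha_c=1.6, trapped=True) == "trapped"
        # both thresholds must be exceeded by default
        assert motility.decide_label(c1=0.98, alpha_c=1.2) == "floating"

    def test_four_class_round_trip(self):
        trajs = synth.gen_class_set(4, seed=40, n_steps=3000)
        pred = [motility.classify(t).label for t in trajs]
        truth = [t.meta["class"] for t in trajs]
        agreement = np.mean([p == t for p, t in zip(pred, truth)])
        assert agreement >= 0.85

    def test_invariance_under_translation_and_rotation(self):
        tr = synth.gen_run_trajectory(
            synth.SwimmerParams(speed=40.0, reversal_rate=0.5), 3000, 1 / 500,
            seed=41)
        base = motility.classify(tr).label
        th = np.deg2rad(33.0)
        xr = tr.x * np.cos(th) - tr.y * np.sin(th) + 12.0
        yr = tr.x * np.sin(th) + tr.y * np.cos(th) - 7.0
        moved = Trajectory(tr.t, xr, yr)
        assert motility.classify(moved).label == base


def test_double_gaussian_separates_two_modes():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(0.0, 0.5, 800), rng.normal(5.0, 0.8, 600)])
    w, m, s = motility.fit_double_gaussian(vals)
    assert m[0] == pytest.approx(0.0, abs=0.2)
    assert m[1] == pytest.approx(5.0, abs=0.3)
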