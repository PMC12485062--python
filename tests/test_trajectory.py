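"""MSD/diffusion estimation, Stokes-Einstein sizing, kinetics and switching."""

import numpy as np
import pytest

from specdim import (
    MSDCurve,
    Trajectory3D,
    compute_msd,
    detect_switch,
    fit_diffusion,
    fit_onset_curve,
    interval_kinetics,
    simulate_motion,
    stokes_einstein_diameter,
    stokes_einstein_diffusion,
)
from specdim.tracking import TrackingRecord


def brute_force_msd(pos, max_lag):
    """Independent double-loop MSD oracle for small n."""
    n = pos.shape[0]
    out = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        acc = 0.0
        for i in range(n - k):
            d = pos[i + k] - pos[i]
            acc += float(d @ d)
        out[k] = acc / (n - k)
    return out


class TestComputeMSD:
    def test_stationary_trajectory_msd_is_zero(self):
        traj = simulate_motion(0.0, 1e-3, 100, seed=0)
        msd = compute_msd(traj)
        assert np.allclose(msd.msd, 0.0)

    def test_ballistic_motion_is_quadratic_in_lag(self):
        v = np.array([1.0, -0.5, 2.0])
        traj = simulate_motion(0.0, 0.01, 200, seed=0, drift_velocity=v)
        msd = compute_msd(traj)
        assert np.allclose(msd.msd, (v @ v) * msd.lags**2, rtol=1e-10)

    def test_equals_brute_force_oracle_exactly(self):
        traj = simulate_motion(1.3, 1e-3, 199, seed=1)
        msd = compute_msd(traj, max_lag_fraction=0.3)
        oracle = brute_force_msd(traj.positions, msd.lags.size - 1)
        assert np.allclose(msd.msd, oracle, rtol=0, atol=1e-12)

    def test_brownian_slope_approximates_6D(self):
        traj = simulate_motion(2.67, 1e-3, 6000, seed=2)
        msd = compute_msd(traj)
        slope = np.polyfit(msd.lags[1:11], msd.msd[1:11], 1)[0]
        assert slope / 6.0 == pytest.approx(2.67, rel=0.15)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 4.0] + list(np.arange(5.0, 25.0)))
        traj = Trajectory3D(t, np.zeros((t.size, 3)))
        with pytest.raises(ValueError):
            compute_msd(traj)


class TestFitDiffusion:
    def _line_curve(self, D, intercept=0.0, dim=3, n=30):
        lags = np.arange(n) * 1e-3
        return MSDCurve(lags, 2 * dim * D * lags + intercept,
                        np.full(n, 100, dtype=int))

    def test_exact_line_recovers_D(self):
        fit = fit_diffusion(self._line_curve(2.67))
        assert fit.D == pytest.approx(2.67, abs=1e-12)

    def test_intercept_decoupled_from_slope(self):
        fit = fit_diffusion(self._line_curve(2.67, intercept=0.01))
        assert fit.D == pytest.approx(2.67, abs=1e-10)
        assert fit.intercept == pytest.approx(0.01, abs=1e-10)

    def test_agrees_with_closed_form_ols(self):
        rng = np.random.default_rng(3)
        lags = np.arange(30) * 1e-3
        y = 6 * 1.5 * lags + rng.normal(0, 1e-4, 30)
        curve = MSDCurve(lags, np.abs(y), np.full(30, 50, dtype=int))
        fit = fit_diffusion(curve, fit_lags=(1, 29))
        tau = lags[1:]
        yy = curve.msd[1:]
        A = np.column_stack([tau, np.ones_like(tau)])
        beta = np.linalg.solve(A.T @ A, A.T @ yy)  # equal weights
        assert fit.D == pytest.approx(beta[0] / 6.0, abs=1e-10)

    def test_invariant_to_rigid_motion(self):
        traj = simulate_motion(1.0, 1e-3, 500, seed=4)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = Trajectory3D(traj.times, traj.positions @ R.T + [5.0, -3.0, 1.0])
        d0 = fit_diffusion(compute_msd(traj)).D
        d1 = fit_diffusion(compute_msd(moved)).D
        assert d1 == pytest.approx(d0, rel=1e-10)

    def test_median_recovery_within_10pct_across_seeds(self):
        # parameter recovery across seeds at three diffusion coefficients
        for D in (0.1, 1.0, 2.67):
            errs = []
            for seed in range(20):
                traj = simulate_motion(D, 1e-3, 6000, seed=seed)
                fit = fit_diffusion(compute_msd(traj, max_lag_fraction=0.05))
                errs.append(abs(fit.D - D) / D)
            assert np.median(errs) < 0.10


class TestStokesEinstein:
    def test_glycerol_single_dye_worked_example(self):
        # D = 2.67 um^2/s in 90 wt% glycerol near room temperature
        d = stokes_einstein_diameter(2.67, temperature=296.0, viscosity=0.183)
        assert d == pytest.approx(0.89, abs=0.02)

    def test_doubling_viscosity_halves_diameter(self):
        d1 = stokes_einstein_diameter(1.0, 296.0, 0.1)
        d2 = stokes_einstein_diameter(1.0, 296.0, 0.2)
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_round_trip_with_inverse(self):
        D = stokes_einstein_diffusion(1.0, 298.0, 0.00089)
        assert stokes_einstein_diameter(D, 298.0, 0.00089) == pytest.approx(1.0, abs=1e-9)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein_diameter(0.0, 296.0, 0.183)


def _record(times, pos):
    n = times.size
    return TrackingRecord(times, pos, pos.copy(), np.zeros((n, 3)),
                          np.ones(n, dtype=int), np.ones(n, dtype=bool))


class TestIntervalKinetics:
    def test_pure_vertical_motion_at_printed_bleb_speed(self):
        # 0.45 um/min vertical, zero translational
        t = np.arange(0, 300.0, 0.5)
        pos = np.zeros((t.size, 3))
        pos[:, 2] = 0.45 / 60.0 * t
        summary = interval_kinetics(_record(t, pos), window=60.0)
        assert np.allclose(summary.vertical_speed, 0.45, atol=1e-9)
        assert np.allclose(summary.translational_speed, 0.0, atol=1e-9)

    def test_linear_spectral_drift_rate_recovered_every_window(self):
        # lambda(t) = 600 - 0.65 * (t/60) nm -> -0.65 nm/min in each window
        t = np.arange(0, 300.0, 0.5)
        pos = np.zeros((t.size, 3))
        series = np.column_stack([t, 600.0 - 0.65 * (t / 60.0)])
        summary = interval_kinetics(_record(t, pos), series, window=60.0)
        assert np.allclose(summary.spectral_rate, -0.65, atol=1e-9)

    def test_stationary_constant_series_all_rates_zero(self):
        t = np.arange(0, 200.0, 1.0)
        pos = np.zeros((t.size, 3))
        series = np.column_stack([t, np.full(t.size, 600.0)])
        summary = interval_kinetics(_record(t, pos), series, window=60.0)
        for arr in (summary.vertical_speed, summary.translational_speed,
                    summary.spectral_rate):
            assert np.allclose(arr, 0.0, atol=1e-12)

    def test_window_longer_than_record_rejected(self):
        t = np.arange(0, 30.0, 1.0)
        with pytest.raises(ValueError):
            interval_kinetics(_record(t, np.zeros((t.size, 3))), window=60.0)


def two_segment_split_oracle(lam):
    """Best single split by exhaustive two-segment mean fit (small n)."""
    n = lam.size
    best, best_sse = None, np.inf
    for k in range(2, n - 2):
        sse = lam[:k].var() * k + lam[k:].var() * (n - k)
        if sse < best_sse:
            best, best_sse = k, sse
    return best, best_sse


class TestDetectSwitch:
    def test_single_step_found_at_the_right_index(self):
        rng = np.random.default_rng(60)
        lam = np.concatenate([np.full(500, 560.0), np.full(500, 515.0)])
        lam += rng.normal(0, 1.0, 1000)
        series = np.column_stack([np.arange(1000) * 0.01, lam])
        cps = detect_switch(series, min_jump=5.0, window=25)
        assert len(cps) == 1
        assert abs(cps[0] - 500) <= 25

    def test_constant_series_yields_no_change_points(self):
        rng = np.random.default_rng(61)
        lam = 600.0 + rng.normal(0, 1.0, 400)
        assert detect_switch(np.column_stack([np.arange(400.0), lam])) == []

    def test_slow_drift_is_not_a_switch(self):
        # a drift whose per-window change stays below min_jump must not fire,
        # consistent with the exhaustive two-segment oracle finding no sharp step
        rng = np.random.default_rng(62)
        n = 200
        lam = 600.0 - 0.01 * np.arange(n) + rng.normal(0, 0.5, n)
        series = np.column_stack([np.arange(float(n)), lam])
        assert detect_switch(series, min_jump=5.0, window=25) == []
        k, sse = two_segment_split_oracle(lam)
        jump = abs(lam[:k].mean() - lam[k:].mean())
        assert jump < 5.0  # the best split the oracle can find is below min_jump

    def test_oracle_confirms_detected_step_location(self):
        rng = np.random.default_rng(63)
        n = 200
        lam = np.where(np.arange(n) < 120, 560.0, 540.0) + rng.normal(0, 1.0, n)
        series = np.column_stack([np.arange(float(n)), lam])
        cps = detect_switch(series, min_jump=5.0, window=20)
        k, _ = two_segment_split_oracle(lam)
        assert len(cps) == 1
        assert abs(cps[0] - k) <= 20

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_switch(np.column_stack([np.arange(10.0), np.zeros(10)]), window=25)


class TestFitOnsetCurve:
    def test_full_conversion_half_time_is_ln2_over_b(self):
        from specdim import OnsetFit

        # closed form at a = 1: y = 1 - exp(-b x) crosses 0.5 at ln2/b
        curve = OnsetFit(1.0, 0.01, -np.log(1 - 0.5 / 1.0) / 0.01)
        assert curve.half_time == pytest.approx(np.log(2) / 0.01, rel=1e-12)
        assert curve(curve.half_time) == pytest.approx(0.5, abs=1e-12)
        # a fitted full-conversion cohort satisfies the same definition
        rng = np.random.default_rng(64)
        times = rng.exponential(100.0, 400)
        fit = fit_onset_curve(times, observation_span=2000.0)
        assert fit.a > 0.9
        assert fit.half_time == pytest.approx(-np.log(1 - 0.5 / fit.a) / fit.b,
                                              rel=1e-9)

    def test_parameter_recovery_within_10pct(self):
        # events drawn with a = 0.9, b = 0.004 /s from n = 200 tracks
        rng = np.random.default_rng(65)
        a_true, b_true, n = 0.9, 0.004, 200
        onsets = rng.exponential(1.0 / b_true, size=rng.binomial(n, a_true))
        fit = fit_onset_curve(onsets, observation_span=3000.0, n_total=n)
        assert fit.a == pytest.approx(a_true, rel=0.10)
        assert fit.b == pytest.approx(b_true, rel=0.10)
        expected_half = -np.log(1 - 0.5 / a_true) / b_true
        assert fit.half_time == pytest.approx(expected_half, rel=0.10)

    def test_half_time_satisfies_its_definition(self):
        rng = np.random.default_rng(66)
        times = rng.exponential(200.0, 300)
        fit = fit_onset_curve(times, observation_span=3000.0)
        if fit.half_time is not None:
            assert fit(fit.half_time) == pytest.approx(0.5, abs=1e-9)

    def test_low_asymptote_leaves_half_time_undefined(self):
        rng = np.random.default_rng(67)
        onsets = rng.exponential(100.0, size=40)
        fit = fit_onset_curve(onsets, observation_span=2000.0, n_total=100)
        assert fit.a < 0.5 and fit.half_time is None

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fit_onset_curve(np.array([1.0, 2.0]), 100.0)
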