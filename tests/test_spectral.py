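"""Profile extraction, Gaussian peak localization, QC and precision metrics."""

import numpy as np
import pytest

from specdim import (
    FramePair,
    InsufficientSeriesError,
    LocalizationResult,
    SpectralProfile,
    apply_learned_localizer,
    extract_profile,
    fit_peak_gaussian,
    precision_series,
    qc_filter,
    train_localizer,
)
from tests.conftest import render_peak_frames


def make_profile(mu=600.0, sigma=15.0, amp=100.0, offset=0.0, noise=None, seed=0,
                 grid=None):
    grid = np.arange(450.0, 751.0) if grid is None else grid
    y = amp * np.exp(-((grid - mu) ** 2) / (2 * sigma**2)) + offset
    if noise is not None:
        y = np.random.default_rng(seed).poisson(np.clip(y, 0, None)).astype(float)
    return SpectralProfile(grid, y, total_photons=float(y.sum()))


class TestExtractProfile:
    def test_monochromatic_stripe_peaks_at_known_wavelength(self, camera, dispersion,
                                                            calibration):
        frames = render_peak_frames(1, 200_000, 561.0, camera, dispersion,
                                    seed=10, width_nm=2.0)
        prof = extract_profile(frames[0], calibration)
        assert prof.wavelengths[np.argmax(prof.intensities)] == pytest.approx(561.0, abs=1.5)

    def test_dark_frame_profile_is_flat_zero(self, camera, dispersion, calibration):
        bright = render_peak_frames(1, 100_000, 600.0, camera, dispersion, seed=11)[0]
        rng = np.random.default_rng(12)
        dark_spec = np.round(rng.normal(camera.baseline_offset, camera.read_noise,
                                        camera.frame_shape)).astype(np.uint16)
        fp = FramePair(bright.reference_image, dark_spec, camera=camera)
        prof = extract_profile(fp, calibration, stripe_rows=(11, 22))
        sem = prof.intensities.std() / np.sqrt(prof.intensities.size)
        assert abs(prof.intensities.mean()) < 5 * sem + 1.0

    def test_profile_linear_in_stripe_intensity(self, camera, dispersion, calibration):
        f1 = render_peak_frames(1, 50_000, 620.0, camera, dispersion, seed=13)[0]
        f2 = render_peak_frames(1, 100_000, 620.0, camera, dispersion, seed=13)[0]
        p1 = extract_profile(f1, calibration)
        p2 = extract_profile(f2, calibration)
        ratio = p2.intensities.sum() / p1.intensities.sum()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_missing_reference_spot_raises(self, camera, dispersion, calibration):
        rng = np.random.default_rng(14)
        noise = rng.normal(camera.baseline_offset, camera.read_noise,
                           camera.frame_shape).astype(np.uint16)
        fp = FramePair(noise, noise.copy(), camera=camera)
        with pytest.raises(ValueError, match="anchor"):
            extract_profile(fp, calibration)


class TestFitPeakGaussian:
    def test_exact_gaussian_recovered_to_machine_precision(self):
        res = fit_peak_gaussian(make_profile(mu=600.0, sigma=15.0))
        assert res.peak_wavelength == pytest.approx(600.0, abs=1e-6)
        assert res.width == pytest.approx(15.0, abs=1e-6)
        assert res.fit_error < 1e-8
        assert res.converged

    def test_shift_equivariance(self):
        p = make_profile(mu=600.0, noise=True, seed=1)
        delta = 37.0
        shifted = SpectralProfile(p.wavelengths + delta, p.intensities)
        a = fit_peak_gaussian(p)
        b = fit_peak_gaussian(shifted)
        assert b.peak_wavelength - a.peak_wavelength == pytest.approx(delta, abs=1e-9)

    def test_spread_matches_grid_search_mle_oracle(self):
        # Poisson-noised Gaussians: the fitted-mu spread must match a
        # brute-force (mu, sigma, A) grid-search oracle within 10%
        grid = np.arange(450.0, 751.0)
        mus_fit, mus_oracle = [], []
        mu_grid = np.linspace(645, 649, 81)
        sg_grid = np.linspace(12, 18, 13)
        shapes = np.stack([
            np.exp(-((grid - m) ** 2) / (2 * s**2))
            for m in mu_grid for s in sg_grid])  # (Nm*Ns, L)
        for seed in range(200):
            p = make_profile(mu=647.0, sigma=15.0, amp=10_000 / (15 * np.sqrt(2 * np.pi)),
                             noise=True, seed=seed)
            mus_fit.append(fit_peak_gaussian(p).peak_wavelength)
            y = p.intensities
            # best least-squares amplitude per shape, then best (mu, sigma)
            num = shapes @ y
            den = np.einsum("ij,ij->i", shapes, shapes)
            sse = (y @ y) - num**2 / den
            mus_oracle.append(mu_grid[np.argmin(sse) // sg_grid.size])
        spread_fit = np.std(mus_fit, ddof=1)
        spread_oracle = np.std(mus_oracle, ddof=1)
        assert spread_fit == pytest.approx(spread_oracle, rel=0.10)

    def test_bimodal_profile_flagged_by_elevated_fit_error(self):
        grid = np.arange(450.0, 751.0)
        y = (np.exp(-((grid - 520.0) ** 2) / (2 * 12.0**2))
             + np.exp(-((grid - 660.0) ** 2) / (2 * 12.0**2))) * 100.0
        res = fit_peak_gaussian(SpectralProfile(grid, y))
        assert res.fit_error > 0.3

    def test_too_few_points_rejected(self):
        grid = np.arange(450.0, 751.0)
        y = np.zeros_like(grid)
        y[100:103] = 5.0
        with pytest.raises(ValueError):
            fit_peak_gaussian(SpectralProfile(grid, y))


class TestQCFilter:
    def test_bright_centered_frame_passes(self, camera, dispersion):
        fp = render_peak_frames(1, 100_000, 600.0, camera, dispersion, seed=20)[0]
        good = LocalizationResult(600.0, 15.0, 100.0, 0.0, 0.05, True)
        rep = qc_filter(fp, position_fit_error=0.05, spectral_result=good)
        assert rep.passed and rep.reasons == ()

    def test_fit_error_just_above_cutoff_fails(self, camera, dispersion):
        fp = render_peak_frames(1, 100_000, 600.0, camera, dispersion, seed=21)[0]
        bad = LocalizationResult(600.0, 15.0, 100.0, 0.0, 0.31, True)
        rep = qc_filter(fp, position_fit_error=0.0, spectral_result=bad)
        assert not rep.passed and rep.reasons == ("spectral_fit_error",)

    def test_position_fit_error_above_cutoff_fails(self, camera, dispersion):
        fp = render_peak_frames(1, 100_000, 600.0, camera, dispersion, seed=22)[0]
        good = LocalizationResult(600.0, 15.0, 100.0, 0.0, 0.05, True)
        rep = qc_filter(fp, position_fit_error=0.35, spectral_result=good)
        assert rep.reasons == ("position_fit_error",)

    def test_dark_frame_fails_low_central_signal(self, camera, dispersion):
        fp = render_peak_frames(1, 0, 600.0, camera, dispersion, seed=23)[0]
        good = LocalizationResult(600.0, 15.0, 100.0, 0.0, 0.05, True)
        rep = qc_filter(fp, position_fit_error=0.0, spectral_result=good)
        assert "low_central_signal" in rep.reasons

    def test_partition_every_frame_passed_xor_failed(self, camera, dispersion):
        # QC is a partition: each frame is in exactly one of {passed, failed}
        rng = np.random.default_rng(24)
        frames = render_peak_frames(10, 40_000, 600.0, camera, dispersion, seed=25)
        frames += render_peak_frames(5, 0, 600.0, camera, dispersion, seed=26)
        n_pass = n_fail = 0
        for fp in frames:
            err = float(rng.uniform(0, 0.6))
            res = LocalizationResult(600.0, 15.0, 100.0, 0.0, err, True)
            rep = qc_filter(fp, position_fit_error=0.0, spectral_result=res)
            assert rep.passed == (len(rep.reasons) == 0)
            n_pass += rep.passed
            n_fail += not rep.passed
        assert n_pass + n_fail == len(frames)


class TestPrecisionSeries:
    def _results(self, peaks):
        return [LocalizationResult(p, 15.0, 100.0, 0.0, 0.01, True) for p in peaks]

    def test_constant_series_has_zero_precision(self):
        out = precision_series(self._results(np.full(50, 647.0)))
        assert out["precision_nm"] == 0.0

    def test_recovers_the_generating_scatter(self):
        # series drawn at the instrument-scale 1.11 nm scatter around 647 nm
        rng = np.random.default_rng(30)
        peaks = rng.normal(647.0, 1.11, 500)
        out = precision_series(self._results(peaks))
        # std estimator SE ~ sigma/sqrt(2(n-1))
        assert out["precision_nm"] == pytest.approx(1.11, abs=4 * 1.11 / np.sqrt(998))

    def test_insufficient_series_signalled(self):
        with pytest.raises(InsufficientSeriesError):
            precision_series(self._results(np.full(5, 647.0)))

    def test_binning_by_photons_produces_curve(self):
        rng = np.random.default_rng(31)
        photons = np.repeat([1e3, 1e4, 1e5], 60)
        peaks = np.concatenate([rng.normal(647, 15 / np.sqrt(n), 60)
                                for n in (1e3, 1e4, 1e5)])
        out = precision_series(self._results(peaks), photon_counts=photons, n_bins=3)
        prec = out["precision_vs_photons_nm"]
        assert len(prec) == 3
        assert prec[0] > prec[1] > prec[2]


class TestLearnedLocalizer:
    def _profiles(self, n, rng, photons=10_000):
        grid = np.arange(450.0, 751.0)
        peaks = rng.uniform(560.0, 700.0, n)
        profs = []
        for mu in peaks:
            lam = rng.normal(mu, 15.0, photons)
            y, _ = np.histogram(lam, bins=np.arange(449.5, 751.5))
            profs.append(SpectralProfile(grid, y.astype(float)))
        return profs, peaks

    def test_matches_gaussian_fit_at_high_photons(self):
        rng = np.random.default_rng(40)
        train, targets = self._profiles(1500, rng)
        model = train_localizer(train, targets)
        test, truth = self._profiles(200, rng)
        err_learned = [apply_learned_localizer(p, model).peak_wavelength - t
                       for p, t in zip(test, truth)]
        err_gauss = [fit_peak_gaussian(p).peak_wavelength - t
                     for p, t in zip(test, truth)]
        assert np.std(err_learned) <= 1.2 * np.std(err_gauss)

    def test_untrained_handle_raises_for_fallback(self):
        from specdim import LearnedLocalizer

        with pytest.raises(RuntimeError):
            apply_learned_localizer(make_profile(), LearnedLocalizer())
        with pytest.raises(RuntimeError):
            apply_learned_localizer(make_profile(), None)

    def test_inference_is_deterministic(self):
        rng = np.random.default_rng(41)
        train, targets = self._profiles(200, rng)
        model = train_localizer(train, targets)
        p = train[0]
        a = apply_learned_localizer(p, model).peak_wavelength
        b = apply_learned_localizer(p, model).peak_wavelength
        assert a == b
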