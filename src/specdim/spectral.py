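"""Per-frame spectral analysis: profile extraction, peak localization, QC.

The peak emission wavelength of each frame is the center of a Gaussian
fitted to the extracted intensity-vs-wavelength profile; its standard
deviation across frames defines the spectral localization precision.
Frames with weak central signal in the position image, or with fitting
errors above 0.3 in either channel, are excluded before precision is
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .calibration import CalibrationCurve, _background_subtract, _windowed_centroid
from .camera import FramePair

__all__ = [
    "SpectralProfile",
    "LocalizationResult",
    "QCReport",
    "InsufficientSeriesError",
    "extract_profile",
    "fit_peak_gaussian",
    "qc_filter",
    "precision_series",
    "LearnedLocalizer",
    "train_localizer",
    "apply_learned_localizer",
]

#: Fit-error cutoff above which a frame is discarded by quality control.
FIT_ERROR_CUTOFF = 0.3


class InsufficientSeriesError(RuntimeError):
    """Raised when too few localizations are available for a precision estimate."""


@dataclass(frozen=True)
class SpectralProfile:
    """Background-subtracted intensity vs wavelength on a uniform nm grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    total_photons: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.size > 2 and not np.allclose(np.diff(lam), lam[1] - lam[0]):
            raise ValueError("wavelength grid must be uniform")
        if np.asarray(self.intensities).size != lam.size:
            raise ValueError("intensities must match wavelength grid")


@dataclass(frozen=True)
class LocalizationResult:
    """Fitted Gaussian peak parameters for one spectral profile.

    ``fit_error`` is RMSE of the fit residuals divided by the fitted
    amplitude — scale-free, so a single cutoff applies across intensities.
    """

    peak_wavelength: float
    width: float
    amplitude: float
    offset: float
    fit_error: float
    converged: bool
    frame_index: int = 0


@dataclass(frozen=True)
class QCReport:
    frame_index: int
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when reasons is empty")


def extract_profile(
    frame: FramePair,
    curve: CalibrationCurve,
    stripe_rows: tuple[int, int] | None = None,
    grid_step_nm: float = 1.0,
    corner: int = 10,
) -> SpectralProfile:
    """Extract the intensity-vs-wavelength profile from one frame pair.

    The per-pixel background (median of four ``corner`` x ``corner`` corner
    blocks) is subtracted from the spectral image, the stripe rows are
    summed per column, and columns are mapped to wavelength through the
    calibration anchored at the reference-spot centroid. The per-column
    signal is divided by the local nm-per-column Jacobian and resampled
    onto a uniform wavelength grid.
    """
    ref_bg, _, ref_noise = _background_subtract(frame.reference_image, corner)
    if ref_bg.max() <= 5.0 * max(ref_noise, 1e-12):
        raise ValueError("no anchor: reference spot not found above background")
    _, anchor_col = _windowed_centroid(ref_bg)

    spec_bg, _, _ = _background_subtract(frame.spectral_image, corner)
    nr, nc = spec_bg.shape
    if stripe_rows is None:
        r0 = int(np.argmax(spec_bg.sum(axis=1)))
        half = 4
        stripe_rows = (max(0, r0 - half), min(nr, r0 + half + 1))
    band = spec_bg[stripe_rows[0]:stripe_rows[1]]
    per_col = band.sum(axis=0)

    cols = np.arange(nc, dtype=float)
    shifts = cols - anchor_col
    model = curve.dispersion
    edge = model.shift(np.array(model.band))
    in_band = (shifts >= min(edge)) & (shifts <= max(edge))
    lam_cols = model.invert(shifts[in_band])
    sig = per_col[in_band]
    # photons-per-column -> per-nm density via the dispersion Jacobian
    dpx_dlam = np.gradient(model.shift(lam_cols), lam_cols)
    density = sig * np.abs(dpx_dlam)

    order = np.argsort(lam_cols)
    lam_sorted, dens_sorted = lam_cols[order], density[order]
    lo, hi = model.band
    grid = np.arange(lo, hi + grid_step_nm / 2, grid_step_nm)
    intens = np.interp(grid, lam_sorted, dens_sorted, left=0.0, right=0.0)

    gain = frame.camera.em_gain if frame.camera.em_gain > 0 else 1.0
    total_photons = max(float(per_col[in_band].sum()) / gain, 0.0)
    return SpectralProfile(grid, intens, total_photons=total_photons,
                           frame_index=frame.frame_index)


def _gaussian(lam, amp, mu, sigma, offset):
    return amp * np.exp(-((lam - mu) ** 2) / (2.0 * sigma**2)) + offset


def fit_peak_gaussian(profile: SpectralProfile) -> LocalizationResult:
    """Fit A*exp(-(lam-mu)^2/(2 sigma^2)) + b to a profile by least squares.

    Initialized from the intensity-weighted centroid and spread; the peak
    emission wavelength is the fitted mu. Non-convergence is reported via
    ``converged=False`` with the initial-moment values retained so QC can
    discard the frame.
    """
    lam = profile.wavelengths
    y = np.asarray(profile.intensities, dtype=float)
    if np.count_nonzero(y > 0) < 5:
        raise ValueError("profile needs >= 5 points above background")
    w = np.clip(y - y.min(), 0.0, None)
    mu0 = float((w * lam).sum() / w.sum())
    sigma0 = float(np.sqrt((w * (lam - mu0) ** 2).sum() / w.sum())) or 1.0
    p0 = [float(y.max() - y.min()), mu0, sigma0, float(y.min())]
    try:
        popt, _ = curve_fit(_gaussian, lam, y, p0=p0, maxfev=5000)
        amp, mu, sigma, off = popt
        sigma = abs(float(sigma))
        resid = y - _gaussian(lam, *popt)
        fit_error = float(np.sqrt(np.mean(resid**2)) / abs(amp)) if amp != 0 else np.inf
        converged = bool(np.isfinite(popt).all()) and amp > 0
        return LocalizationResult(float(mu), sigma, float(amp), float(off),
                                  fit_error, converged, profile.frame_index)
    except RuntimeError:
        resid = y - _gaussian(lam, *p0)
        fit_error = float(np.sqrt(np.mean(resid**2)) / max(p0[0], 1e-12))
        return LocalizationResult(mu0, sigma0, p0[0], p0[3], fit_error, False,
                                  profile.frame_index)


def qc_filter(
    frame: FramePair,
    position_fit_error: float,
    spectral_result: LocalizationResult,
    threshold_ratio: float = 2.0,
    cutoff: float = FIT_ERROR_CUTOFF,
    corner: int = 10,
) -> QCReport:
    """Quality control for one frame.

    Fails with ``low_central_signal`` when the mean of the central 5x5
    region of the position (reference) image does not exceed
    ``threshold_ratio`` times the corner-estimated background, and with
    ``position_fit_error`` / ``spectral_fit_error`` when either channel's
    fitting error exceeds the cutoff (0.3).
    """
    img = np.asarray(frame.reference_image, dtype=float)
    nr, nc = img.shape
    if nr < 15 or nc < 15:
        raise ValueError("frame too small for central 5x5 / corner QC")
    r0, c0 = nr // 2 - 2, nc // 2 - 2
    central = img[r0:r0 + 5, c0:c0 + 5].mean()
    c = min(corner, nr // 2, nc // 2)
    bg = np.median(np.concatenate([
        img[:c, :c].ravel(), img[:c, -c:].ravel(),
        img[-c:, :c].ravel(), img[-c:, -c:].ravel()]))

    reasons: list[str] = []
    if central < threshold_ratio * max(bg, 1e-12):
        reasons.append("low_central_signal")
    if position_fit_error > cutoff:
        reasons.append("position_fit_error")
    if spectral_result.fit_error > cutoff or not spectral_result.converged:
        reasons.append("spectral_fit_error")
    return QCReport(frame.frame_index, passed=not reasons, reasons=tuple(reasons))


def precision_series(
    results,
    photon_counts=None,
    n_bins: int = 5,
    min_results: int = 10,
) -> dict:
    """Spectral localization precision from a series of peak localizations.

    Precision is the standard deviation of the fitted peak wavelength over
    the supplied (QC-passed) frames. With ``photon_counts`` given, frames
    are additionally binned by photon count (log-spaced) to produce a
    precision-vs-photons curve.
    """
    peaks = np.asarray([r.peak_wavelength for r in results], dtype=float)
    if peaks.size < min_results:
        raise InsufficientSeriesError(
            f"{peaks.size} localizations < required {min_results}")
    out = {
        "precision_nm": float(np.std(peaks, ddof=1)),
        "mean_peak_nm": float(np.mean(peaks)),
        "n": int(peaks.size),
    }
    if photon_counts is not None:
        n = np.asarray(photon_counts, dtype=float)
        edges = np.geomspace(max(n.min(), 1.0), n.max() * (1 + 1e-9), n_bins + 1)
        centers, prec, counts = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (n >= lo) & (n < hi)
            if sel.sum() >= 3:
                centers.append(float(np.sqrt(lo * hi)))
                prec.append(float(np.std(peaks[sel], ddof=1)))
                counts.append(int(sel.sum()))
        out["photons_bin_center"] = centers
        out["precision_vs_photons_nm"] = prec
        out["bin_counts"] = counts
    return out


# ---------------------------------------------------------------------------
# Optional learned localizer: a small ridge regressor on normalized profiles.
# Stands in for learned peak detectors operating on the spectral stripe; the
# pipeline falls back to Gaussian fitting whenever no trained model is given.
# ---------------------------------------------------------------------------


@dataclass
class LearnedLocalizer:
    weights: np.ndarray | None = None
    bias: float = 0.0
    grid: np.ndarray | None = None

    @property
    def trained(self) -> bool:
        return self.weights is not None


def _profile_features(profile: SpectralProfile, grid: np.ndarray) -> np.ndarray:
    y = np.interp(grid, profile.wavelengths, np.clip(profile.intensities, 0, None))
    s = y.sum()
    return y / s if s > 0 else y


def train_localizer(profiles, true_peaks, ridge: float = 1e-6) -> LearnedLocalizer:
    """Fit a ridge regression from normalized profiles to true peak wavelengths."""
    grid = np.asarray(profiles[0].wavelengths, dtype=float)
    X = np.stack([_profile_features(p, grid) for p in profiles])
    y = np.asarray(true_peaks, dtype=float)
    Xb = X - X.mean(axis=0)
    yb = y - y.mean()
    A = Xb.T @ Xb + ridge * np.eye(X.shape[1])
    w = np.linalg.solve(A, Xb.T @ yb)
    bias = float(y.mean() - X.mean(axis=0) @ w)
    return LearnedLocalizer(weights=w, bias=bias, grid=grid)


def apply_learned_localizer(profile: SpectralProfile,
                            model_handle: LearnedLocalizer | None) -> LocalizationResult:
    """Predict the peak wavelength with a trained localizer.

    Raises ``RuntimeError`` when the handle is missing or untrained so the
    caller can fall back to :func:`fit_peak_gaussian`. Inference is
    deterministic: identical inputs give identical outputs.
    """
    if model_handle is None or not model_handle.trained:
        raise RuntimeError("learned localizer unavailable; use Gaussian fitting")
    x = _profile_features(profile, model_handle.grid)
    mu = float(x @ model_handle.weights + model_handle.bias)
    return LocalizationResult(mu, width=np.nan, amplitude=float(np.max(profile.intensities)),
                              offset=0.0, fit_error=0.0, converged=True,
                              frame_index=profile.frame_index)
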