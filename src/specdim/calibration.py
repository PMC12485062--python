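"""Wavelength <-> pixel calibration and reference/spectral channel registration.

The spectral stripe is registered against the reference spot by sub-pixel
center of mass on background-subtracted images; known emission peaks then
pin down the pixel-shift polynomial of the prism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .camera import DispersionModel

__all__ = [
    "CalibrationCurve",
    "EmptyFrameError",
    "register_channels",
    "fit_dispersion",
    "pixel_to_wavelength",
    "wavelength_to_pixel",
]


class EmptyFrameError(RuntimeError):
    """Raised when a calibration frame contains no signal above background."""


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted dispersion model plus fit diagnostics.

    ``anchor_column`` is the reference-spot centroid column the shifts are
    measured against; ``residuals_nm`` the per-point wavelength residuals.
    """

    dispersion: DispersionModel
    residuals_nm: np.ndarray
    anchor_column: float = 0.0

    @property
    def residual_rms_nm(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_nm**2))) if self.residuals_nm.size else 0.0


def _background_subtract(image: np.ndarray, corner: int = 10) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    c = min(corner, img.shape[0] // 2, img.shape[1] // 2)
    corners = np.concatenate([
        img[:c, :c].ravel(), img[:c, -c:].ravel(),
        img[-c:, :c].ravel(), img[-c:, -c:].ravel()])
    return img - np.median(corners), float(np.median(corners)), float(np.std(corners))


def _center_of_mass(image_bg: np.ndarray) -> tuple[float, float]:
    pos = np.clip(image_bg, 0.0, None)
    total = pos.sum()
    rows = np.arange(image_bg.shape[0])
    cols = np.arange(image_bg.shape[1])
    r = float((pos.sum(axis=1) * rows).sum() / total)
    c = float((pos.sum(axis=0) * cols).sum() / total)
    return r, c


def _windowed_centroid(image_bg: np.ndarray, halfwidth: int = 8) -> tuple[float, float]:
    """Center of mass restricted to a window around the brightest pixel.

    Excluding far-field pixels keeps clipped read noise from pulling the
    centroid toward the image center — the dominant error for point-like
    spots on large frames.
    """
    r0, c0 = np.unravel_index(np.argmax(image_bg), image_bg.shape)
    r1, r2 = max(0, r0 - halfwidth), min(image_bg.shape[0], r0 + halfwidth + 1)
    c1, c2 = max(0, c0 - halfwidth), min(image_bg.shape[1], c0 + halfwidth + 1)
    win = image_bg[r1:r2, c1:c2]
    r, c = _center_of_mass(win)
    return r + r1, c + c1


def _has_signal(image_bg: np.ndarray, noise: float, min_snr: float = 5.0) -> bool:
    # total excess signal must stand clear of the background noise floor
    return float(image_bg.max()) > min_snr * max(noise, 1e-12)


def register_channels(reference_image: np.ndarray,
                      spectral_image: np.ndarray) -> tuple[float, float]:
    """Sub-pixel (column, row) shift of the spectral stripe vs the reference spot.

    Both images are corner-background subtracted; the shift is the
    difference of their intensity centers of mass. Raises
    :class:`EmptyFrameError` when either channel has no significant signal.
    """
    if reference_image.shape != spectral_image.shape:
        raise ValueError("images must share shape")
    ref_bg, _, ref_noise = _background_subtract(reference_image)
    spec_bg, _, spec_noise = _background_subtract(spectral_image)
    if not (_has_signal(ref_bg, ref_noise) and _has_signal(spec_bg, spec_noise)):
        raise EmptyFrameError("no signal above background in one or both channels")
    r_ref, c_ref = _center_of_mass(ref_bg)
    r_spec, c_spec = _center_of_mass(spec_bg)
    return c_spec - c_ref, r_spec - r_ref


def fit_dispersion(calibration_points, degree: int = 2,
                   band: tuple[float, float] | None = None,
                   anchor_column: float = 0.0) -> CalibrationCurve:
    """Least-squares polynomial fit of pixel shift vs wavelength.

    ``calibration_points`` is a sequence of (wavelength_nm, shift_px) pairs
    from known emission lines. The fitted polynomial must be strictly
    monotone over the span of the calibration wavelengths (extended to
    ``band`` when given); wavelength residuals are obtained by inverting
    the fit at each measured shift.
    """
    pts = np.asarray(calibration_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("calibration_points must be (lambda_nm, shift_px) pairs")
    lam, px = pts[:, 0], pts[:, 1]
    if np.unique(lam).size != lam.size:
        raise ValueError("calibration wavelengths must be distinct")
    if lam.size < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for degree {degree}")
    coeffs = np.polynomial.polynomial.polyfit(lam, px, degree)
    span = band if band is not None else (float(lam.min()), float(lam.max()))
    model = DispersionModel(tuple(coeffs), span)  # raises if non-monotone
    lam_back = model.invert(px)
    return CalibrationCurve(model, residuals_nm=lam_back - lam,
                            anchor_column=anchor_column)


def wavelength_to_pixel(wavelength, curve: CalibrationCurve) -> np.ndarray:
    """Pixel shift (relative to the anchor column) for a wavelength."""
    return curve.dispersion.shift(wavelength)


def pixel_to_wavelength(shift_px, curve: CalibrationCurve,
                        warn_extrapolation: bool = True) -> np.ndarray:
    """Wavelength for a measured column shift, by inverting the monotone fit.

    Shifts outside the calibrated band are clamped to the band edges (an
    extrapolation warning, not a failure).
    """
    shift_px = np.asarray(shift_px, dtype=float)
    model = curve.dispersion
    lo, hi = model.band
    edge = model.shift(np.array([lo, hi]))
    pmin, pmax = min(edge), max(edge)
    if warn_extrapolation and (np.any(shift_px < pmin) or np.any(shift_px > pmax)):
        import warnings

        warnings.warn("pixel shift outside calibrated band; clamping", stacklevel=2)
    return model.invert(shift_px)


def _invert_bisection(model: DispersionModel, shift_px: float) -> float:
    """Reference inversion by root bracketing (used as an independent check)."""
    lo, hi = model.band
    sign = 1.0 if float(model.shift(hi)) > float(model.shift(lo)) else -1.0
    f = lambda lam: sign * (float(model.shift(lam)) - shift_px)
    return brentq(f, lo, hi, xtol=1e-9)
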