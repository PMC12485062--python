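"""Spectral unmixing and ratiometric pH conversion.

A measured profile M is modeled as M = S.C + E where S holds the known
component emission spectra (columns) on the analysis wavelength grid and C
the per-component contributions; C is obtained by least squares,
C = (S^T S)^-1 S^T M. The component-intensity ratio (e.g. a pH-sensitive
fluorophore against a pH-stable one) is converted to pH through a logistic
calibration curve. A wavelength-split band ratio is provided as the
crosstalk-prone baseline these spectral methods improve on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ReferenceSpectra",
    "AbundanceEstimate",
    "PHCalibration",
    "DegenerateReferenceError",
    "UndefinedRatioError",
    "gaussian_reference_spectra",
    "unmix_least_squares",
    "wavelength_split_ratio",
    "ratio_to_ph",
    "ph_to_ratio",
]


class DegenerateReferenceError(ValueError):
    """Reference spectra too collinear to unmix against."""


class UndefinedRatioError(ZeroDivisionError):
    """Band ratio with an (effectively) zero denominator."""


@dataclass(frozen=True)
class ReferenceSpectra:
    """Known component spectra sampled on the analysis wavelength grid.

    ``matrix`` has one column per component, each non-negative and
    normalized to unit sum, so unmixing coefficients are directly
    comparable intensity contributions.
    """

    names: tuple[str, ...]
    matrix: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix, dtype=float)
        g = np.asarray(self.grid, dtype=float)
        if S.shape != (g.size, len(self.names)):
            raise ValueError("matrix must be (n_wavelengths, n_components)")
        if np.any(S < -1e-12):
            raise ValueError("reference spectra must be non-negative")
        colsum = S.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError("each reference spectrum must have positive mass")
        object.__setattr__(self, "matrix", S / colsum)
        object.__setattr__(self, "grid", g)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class AbundanceEstimate:
    """Per-frame component coefficients from unmixing, with diagnostics."""

    coefficients: np.ndarray
    residual_norm: float
    condition_number: float
    frame_index: int = 0


@dataclass(frozen=True)
class PHCalibration:
    """Logistic (Henderson–Hasselbalch form) ratio <-> pH calibration.

    ratio(pH) = R_min + (R_max - R_min) / (1 + 10**(pKa - pH)); the ratio
    decreases monotonically as the environment acidifies.
    """

    r_min: float = 0.2
    r_max: float = 2.5
    pka: float = 5.5

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("require r_min < r_max")


def gaussian_reference_spectra(
    grid: np.ndarray,
    names: tuple[str, ...] = ("mGold", "JF549", "LysoTracker"),
    peaks: tuple[float, ...] = (548.0, 580.0, 670.0),
    widths: tuple[float, ...] = (20.0, 30.0, 20.0),
) -> ReferenceSpectra:
    """Synthetic three-dye reference set (Gaussian emission profiles).

    Defaults emulate a yellow pH-sensitive protein, an orange pH-stable
    dye, and a deep-red lysosome marker with realistic spectral overlap.
    """
    grid = np.asarray(grid, dtype=float)
    cols = [np.exp(-0.5 * ((grid - p) / w) ** 2) for p, w in zip(peaks, widths)]
    return ReferenceSpectra(tuple(names), np.column_stack(cols), grid)


def unmix_least_squares(
    M: np.ndarray,
    S: ReferenceSpectra,
    nonnegative: bool = False,
    max_condition: float = 1e8,
    frame_index: int = 0,
) -> AbundanceEstimate:
    """Solve M = S.C + E for the component contributions C.

    Ordinary least squares via a stable orthogonal factorization (QR-based
    ``lstsq``), equivalent to the normal-equation solution
    (S^T S)^-1 S^T M on well-conditioned inputs; ``nonnegative=True``
    switches to non-negativity-constrained least squares. ``M`` may be a
    single profile or a (n_wavelengths, n_frames) stack.
    """
    A = S.matrix
    M = np.asarray(M, dtype=float)
    if M.shape[0] != A.shape[0]:
        raise ValueError("measurement grid must match reference grid")
    cond = float(np.linalg.cond(A.T @ A))
    if cond > max_condition:
        raise DegenerateReferenceError(
            f"reference set condition number {cond:.3g} exceeds bound {max_condition:.3g}")
    if nonnegative:
        if M.ndim == 1:
            coeff, _ = nnls(A, M)
        else:
            coeff = np.column_stack([nnls(A, M[:, j])[0] for j in range(M.shape[1])])
    else:
        coeff, *_ = np.linalg.lstsq(A, M, rcond=None)
    resid = M - A @ coeff
    return AbundanceEstimate(coeff, float(np.linalg.norm(resid)), cond, frame_index)


def wavelength_split_ratio(
    M: np.ndarray,
    grid: np.ndarray,
    band_a: tuple[float, float] = (500.0, 570.0),
    band_b: tuple[float, float] = (570.0, 640.0),
) -> float:
    """Band-intensity ratio  integral_A M / integral_B M  (rectangle rule).

    This is the conventional two-channel ratiometric readout; spectral
    crosstalk between overlapping emitters biases it, which is what
    unmixing corrects.
    """
    grid = np.asarray(grid, dtype=float)
    M = np.asarray(M, dtype=float)
    if band_a[1] > band_b[0] and band_b[1] > band_a[0]:
        raise ValueError("bands must be disjoint")
    in_a = (grid >= band_a[0]) & (grid < band_a[1])
    in_b = (grid >= band_b[0]) & (grid < band_b[1])
    num = float(M[in_a].sum())
    den = float(M[in_b].sum())
    if den <= 0:
        raise UndefinedRatioError("zero intensity in denominator band")
    return num / den


def ph_to_ratio(ph: np.ndarray, cal: PHCalibration) -> np.ndarray:
    """Forward calibration: intensity ratio expected at a given pH."""
    ph = np.asarray(ph, dtype=float)
    return cal.r_min + (cal.r_max - cal.r_min) / (1.0 + 10.0 ** (cal.pka - ph))


def ratio_to_ph(ratio, cal: PHCalibration) -> np.ndarray:
    """Invert the calibration: pH = pKa - log10((R_max - r) / (r - R_min)).

    Strictly increasing in the ratio. Ratios outside (R_min, R_max) are
    clamped just inside the open interval with a warning (the calibration
    saturates there); exact boundary values would map to +-infinity.
    """
    r = np.atleast_1d(np.asarray(ratio, dtype=float))
    eps = 1e-6 * (cal.r_max - cal.r_min)
    if np.any(r <= cal.r_min + eps) or np.any(r >= cal.r_max - eps):
        warnings.warn("ratio outside calibrated range; clamping", stacklevel=2)
    r = np.clip(r, cal.r_min + eps, cal.r_max - eps)
    ph = cal.pka - np.log10((cal.r_max - r) / (r - cal.r_min))
    return ph if np.asarray(ratio).ndim else float(ph[0])
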