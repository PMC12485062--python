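"""EMCCD forward model: paired reference / prism-dispersed spectral frames.

Detected photons are split between a reference channel (a point image of
the emitter) and a spectral channel, where a prism displaces each photon
along the column axis by a wavelength-dependent pixel shift. Photoelectrons
pass a stochastic electron-multiplying register (Gamma approximation, which
reproduces the excess-noise factor of 2), then Gaussian read noise and a
fixed baseline, and are digitized to 16-bit counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraConfig",
    "DispersionModel",
    "FramePair",
    "render_frame_pair",
    "frame_timing",
]

BIT_DEPTH_MAX = 65535


@dataclass(frozen=True)
class CameraConfig:
    """EMCCD geometry, timing and noise parameters.

    overhead is shutter-transfer + readout time; the frame period is
    exposure + overhead. The default overhead of 1.5528 ms gives a limiting
    (zero-exposure) rate of ~644 fps for the single-stripe readout mode.
    split_fraction is the fraction of photons routed to the spectral
    channel (a 30/70 splitter sends 70% there).
    """

    pixel_size: float = 100.0  # nm in the sample plane
    frame_shape: tuple[int, int] = (32, 160)
    exposure: float = 1e-3
    overhead: float = 1.5528e-3
    em_gain: float = 60.0
    read_noise: float = 3.0  # electrons RMS (post-gain register, in e-)
    baseline_offset: float = 100.0
    split_fraction: float = 0.7
    quantum_efficiency: float = 1.0
    psf_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        if self.overhead < 0:
            raise ValueError("overhead must be >= 0")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DispersionModel:
    """Pixel shift of the spectral image vs wavelength.

    ``shift(lam) = c0 + c1*lam + c2*lam**2`` (px, lam in nm), strictly
    monotone over the working band so it can be inverted. The default is a
    prism-like quadratic spanning ~120 columns over 450-750 nm, denser
    (more px/nm) at the blue end, with zero shift at 600 nm so the stripe
    straddles the reference column.
    """

    coefficients: tuple[float, ...] = (-420.0, 1.0, -5.0e-4)
    band: tuple[float, float] = (450.0, 750.0)

    def __post_init__(self) -> None:
        lam = np.linspace(*self.band, 512)
        d = np.diff(self.shift(lam))
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("dispersion must be strictly monotone over the band")

    def shift(self, wavelength: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelength, dtype=float)
        out = np.zeros_like(lam)
        for k, c in enumerate(self.coefficients):
            out = out + c * lam**k
        return out

    def invert(self, shift_px: np.ndarray) -> np.ndarray:
        """Wavelength for a given pixel shift by monotone interpolation."""
        lam = np.linspace(*self.band, 4096)
        px = self.shift(lam)
        if px[0] > px[-1]:
            lam, px = lam[::-1], px[::-1]
        return np.interp(np.asarray(shift_px, dtype=float), px, lam)


@dataclass(frozen=True)
class FramePair:
    """One reference image and one spectral-stripe image sharing a timestamp."""

    reference_image: np.ndarray
    spectral_image: np.ndarray
    timestamp: float = 0.0
    frame_index: int = 0
    camera: CameraConfig = field(default_factory=CameraConfig)

    def __post_init__(self) -> None:
        if self.reference_image.shape != self.spectral_image.shape:
            raise ValueError("reference and spectral images must share shape")


def _em_register(electrons: np.ndarray, gain: float, rng: np.random.Generator) -> np.ndarray:
    """Stochastic EM gain: Gamma(n, gain) per pixel (0 stays 0).

    The Gamma approximation to the multi-stage avalanche register has mean
    n*gain and variance n*gain^2, i.e. output variance ~ 2*gain^2*n once
    input shot noise is included — the standard excess-noise factor of 2.
    """
    out = np.zeros_like(electrons, dtype=float)
    nz = electrons > 0
    if nz.any():
        out[nz] = rng.gamma(shape=electrons[nz], scale=gain)
    return out


def _render_channel(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int],
                    camera: CameraConfig, rng: np.random.Generator) -> np.ndarray:
    """Histogram photon landing positions, then apply EM gain + read noise."""
    nr, nc = shape
    r = np.clip(np.round(rows).astype(int), 0, nr - 1)
    c = np.clip(np.round(cols).astype(int), 0, nc - 1)
    electrons = np.zeros(shape, dtype=np.int64)
    np.add.at(electrons, (r, c), 1)
    signal = _em_register(electrons, camera.em_gain, rng)
    noisy = signal + rng.normal(camera.baseline_offset, camera.read_noise, size=shape)
    return np.clip(np.round(noisy), 0, BIT_DEPTH_MAX).astype(np.uint16)


def render_frame_pair(
    residual_offset: np.ndarray,
    spectrum_sampler,
    photon_budget: int,
    camera: CameraConfig,
    dispersion: DispersionModel,
    seed: int | np.random.Generator,
    timestamp: float = 0.0,
    frame_index: int = 0,
    anchor: tuple[float, float] | None = None,
) -> FramePair:
    """Render one reference/spectral frame pair.

    residual_offset — lateral (x, y) emitter-minus-focus offset in um,
    projected through ``pixel_size``; ``spectrum_sampler(n, rng)`` draws n
    emission wavelengths (a :class:`~specdim.particle.SpectrumModel` bound
    at a time, or any callable). Photons are split binomially between the
    channels; each spectral photon lands at the reference column plus the
    dispersion shift of its wavelength, blurred by the same PSF.
    """
    if photon_budget < 0:
        raise ValueError("photon_budget must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nr, nc = camera.frame_shape
    if anchor is None:
        anchor = (nr / 2.0, nc / 2.0)
    row0 = anchor[0] + residual_offset[1] * 1000.0 / camera.pixel_size
    col0 = anchor[1] + residual_offset[0] * 1000.0 / camera.pixel_size

    detected = rng.binomial(photon_budget, camera.quantum_efficiency) \
        if camera.quantum_efficiency < 1 else photon_budget
    n_spec = rng.binomial(detected, camera.split_fraction)
    n_ref = detected - n_spec

    ref_rows = rng.normal(row0, camera.psf_sigma_px, n_ref)
    ref_cols = rng.normal(col0, camera.psf_sigma_px, n_ref)
    reference = _render_channel(ref_rows, ref_cols, camera.frame_shape, camera, rng)

    lam = np.asarray(spectrum_sampler(n_spec, rng), dtype=float)
    lo, hi = dispersion.band
    lam = np.clip(lam, lo, hi)
    spec_rows = rng.normal(row0, camera.psf_sigma_px, n_spec)
    spec_cols = rng.normal(col0 + dispersion.shift(lam), camera.psf_sigma_px)
    spectral = _render_channel(spec_rows, spec_cols, camera.frame_shape, camera, rng)

    return FramePair(reference, spectral, timestamp=timestamp,
                     frame_index=frame_index, camera=camera)


def frame_timing(exposure: float, camera: CameraConfig) -> tuple[float, float]:
    """Frame period and limiting frame rate for a given exposure.

    frame_period = exposure + overhead; the maximum achievable rate (as
    exposure -> 0) is 1 / overhead.
    """
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    frame_period = exposure + camera.overhead
    max_rate = np.inf if camera.overhead == 0 else 1.0 / camera.overhead
    return frame_period, max_rate
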