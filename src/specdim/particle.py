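"""Ground-truth emitter physics: Brownian motion, emission spectra, photon counts.

Units follow the instrument frame throughout the package: positions in
micrometers, times in seconds, wavelengths in nanometers, rates in photons
per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Trajectory3D",
    "SpectrumModel",
    "EmitterModel",
    "ExcitationVolume",
    "PhotonStream",
    "simulate_motion",
    "emit_photons",
    "excitation_factor",
]

#: Working emission band of the spectral channel, nm.
DEFAULT_BAND = (450.0, 750.0)


@dataclass(frozen=True)
class Trajectory3D:
    """A 3D emitter path sampled on an ascending time grid.

    ``positions`` has shape (n, 3) in micrometers; ``times`` in seconds.
    """

    times: np.ndarray
    positions: np.ndarray
    diffusion_coefficient: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if p.shape != (t.size, 3):
            raise ValueError(f"positions shape {p.shape} != ({t.size}, 3)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("non-finite values in trajectory")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpectrumModel:
    """Time-dependent emission spectrum of an emitter.

    kind:
        ``static_gaussian``  — fixed Gaussian peak,
        ``drifting_peak``    — peak wavelength moves at ``drift_rate`` nm/s,
        ``step_peak``        — peak jumps from peaks[0] to peaks[1] at ``step_time``,
        ``mixture``          — weighted sum of Gaussian components whose
                               weights may vary with time via ``weight_fn``.
    """

    kind: str = "static_gaussian"
    peaks: tuple[float, ...] = (647.0,)
    widths: tuple[float, ...] = (15.0,)
    drift_rate: float = 0.0
    step_time: float = 0.0
    component_weights: tuple[float, ...] | None = None
    weight_fn: Callable[[float], Sequence[float]] | None = None
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.kind not in {"static_gaussian", "drifting_peak", "step_peak", "mixture"}:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        lo, hi = self.band
        for p in self.peaks:
            if not (lo <= p <= hi):
                raise ValueError(f"peak {p} nm outside working band {self.band}")
        if len(self.widths) not in (1, len(self.peaks)):
            raise ValueError("widths must be scalar-like or match peaks")
        if self.kind == "mixture" and self.component_weights is not None:
            w = np.asarray(self.component_weights, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture weights must be >= 0 and sum to 1")

    def _width(self, i: int) -> float:
        return self.widths[i] if len(self.widths) > 1 else self.widths[0]

    def weights_at(self, t: float) -> np.ndarray:
        if self.weight_fn is not None:
            w = np.asarray(self.weight_fn(t), dtype=float)
        elif self.component_weights is not None:
            w = np.asarray(self.component_weights, dtype=float)
        else:
            w = np.ones(len(self.peaks))
        return w / w.sum()

    def peak_at(self, t: float) -> float:
        """Nominal peak wavelength at time t (single-peak kinds)."""
        if self.kind == "drifting_peak":
            return self.peaks[0] + self.drift_rate * t
        if self.kind == "step_peak":
            return self.peaks[1] if t >= self.step_time else self.peaks[0]
        return self.peaks[0]

    def sample(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one wavelength per entry of ``times``."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        n = times.size
        if self.kind == "mixture":
            w = np.stack([self.weights_at(t) for t in times])  # (n, k)
            cum = np.cumsum(w, axis=1)
            u = rng.uniform(size=(n, 1))
            comp = (u > cum).sum(axis=1)
            mu = np.asarray(self.peaks)[comp]
            sd = np.asarray([self._width(k) for k in range(len(self.peaks))])[comp]
            return rng.normal(mu, sd)
        mu = np.array([self.peak_at(t) for t in times]) if self.kind != "static_gaussian" \
            else np.full(n, self.peaks[0])
        return rng.normal(mu, self._width(0))

    def density(self, wavelengths: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Emission density on a wavelength grid at time t (integrates to ~1)."""
        lam = np.asarray(wavelengths, dtype=float)
        if self.kind == "mixture":
            w = self.weights_at(t)
            out = np.zeros_like(lam)
            for k, wk in enumerate(w):
                s = self._width(k)
                out += wk * np.exp(-0.5 * ((lam - self.peaks[k]) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            return out
        mu, s = self.peak_at(t), self._width(0)
        return np.exp(-0.5 * ((lam - mu) / s) ** 2) / (s * np.sqrt(2 * np.pi))


@dataclass(frozen=True)
class EmitterModel:
    """Photophysics of one emitter.

    ``peak_rate`` is the detected photon rate (photons/s) with the emitter at
    the excitation-volume center — the analogue of the APD count rate.
    Blinking is a two-state telegraph process, bleaching a one-way
    exponential clock; both default off.
    """

    peak_rate: float = 1e6
    background_rate: float = 0.0
    spectrum: SpectrumModel = field(default_factory=SpectrumModel)
    blink_on_rate: float = 0.0
    blink_off_rate: float = 0.0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("peak_rate", "background_rate", "blink_on_rate",
                     "blink_off_rate", "bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExcitationVolume:
    """Separable-Gaussian excitation volume (1/e^2 radii, micrometers)."""

    waist_xy: float = 0.5
    waist_z: float = 1.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.waist_xy <= 0 or self.waist_z <= 0:
            raise ValueError("waists must be > 0")


@dataclass(frozen=True)
class PhotonStream:
    """Binned detected photons with the scan offset active at detection.

    ``times`` are bin midpoints (s); ``scan_index`` the index of the lateral
    scan offset active in the bin (-1 when no scan); ``counts`` the detected
    photons; ``wavelengths`` an optional per-bin wavelength draw (nm, NaN for
    empty bins).
    """

    times: np.ndarray
    scan_index: np.ndarray
    counts: np.ndarray
    wavelengths: np.ndarray | None = None
    bin_dt: float = 0.0

    def __post_init__(self) -> None:
        n = np.asarray(self.times).size
        for arr in (self.scan_index, self.counts):
            if np.asarray(arr).size != n:
                raise ValueError("photon stream arrays must share length")

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


def excitation_factor(offset: np.ndarray, volume: ExcitationVolume) -> np.ndarray:
    """Relative excitation G(r) = exp(-2(x^2+y^2)/w_xy^2) exp(-2 z^2/w_z^2).

    ``offset`` is emitter position minus focus position, shape (..., 3) um.
    """
    r = np.asarray(offset, dtype=float)
    lat = (r[..., 0] ** 2 + r[..., 1] ** 2) / volume.waist_xy**2
    ax = r[..., 2] ** 2 / volume.waist_z**2
    return np.exp(-2.0 * (lat + ax))


def simulate_motion(
    diffusion_coefficient: float,
    dt: float,
    n_steps: int,
    seed: int,
    drift_velocity: Sequence[float] | None = None,
    start: Sequence[float] = (0.0, 0.0, 0.0),
) -> Trajectory3D:
    """Simulate isotropic Brownian motion with optional constant drift.

    Per-axis increments are independent Gaussians with variance 2*D*dt plus
    ``drift_velocity * dt``. Returns n_steps + 1 samples starting at
    ``start``.
    """
    if diffusion_coefficient < 0:
        raise ValueError("diffusion_coefficient must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * diffusion_coefficient * dt)
    steps = rng.normal(0.0, sigma, size=(n_steps, 3)) if sigma > 0 else np.zeros((n_steps, 3))
    if drift_velocity is not None:
        steps = steps + np.asarray(drift_velocity, dtype=float) * dt
    pos = np.vstack([np.asarray(start, dtype=float), steps]).cumsum(axis=0)
    times = np.arange(n_steps + 1) * dt
    return Trajectory3D(times, pos, diffusion_coefficient=diffusion_coefficient, seed=seed)


def _photophysics_gate(times: np.ndarray, emitter: EmitterModel,
                       rng: np.random.Generator) -> np.ndarray:
    """0/1 emission gate from blinking + bleaching, sampled on ``times``."""
    gate = np.ones(times.size)
    if emitter.blink_off_rate > 0 and emitter.blink_on_rate > 0:
        # telegraph process: simulate alternating exponential dwells
        on = True
        t = times[0]
        idx = 0
        t_end = times[-1]
        while t < t_end and idx < times.size:
            rate = emitter.blink_off_rate if on else emitter.blink_on_rate
            dwell = rng.exponential(1.0 / rate)
            nxt = t + dwell
            j = np.searchsorted(times, nxt)
            if not on:
                gate[idx:j] = 0.0
            idx, t, on = j, nxt, not on
    if emitter.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / emitter.bleach_rate)
        gate[times >= times[0] + t_bleach] = 0.0
    return gate


def emit_photons(
    trajectory: Trajectory3D,
    emitter: EmitterModel,
    volume: ExcitationVolume,
    focus_path: np.ndarray | None,
    bin_dt: float,
    seed: int,
    scan_index: np.ndarray | None = None,
    draw_wavelengths: bool = False,
) -> PhotonStream:
    """Draw Poisson photon counts modulated by displacement from the focus.

    ``focus_path`` gives the instantaneous focus center per trajectory sample
    (shape (n, 3) um); None means a fixed focus at ``volume.center``. Counts
    are binned at ``bin_dt`` (must not exceed the trajectory step). With
    ``draw_wavelengths`` each non-empty bin carries one wavelength drawn from
    the emitter spectrum at the bin time.
    """
    traj_dt = trajectory.dt
    if bin_dt > traj_dt * (1 + 1e-9):
        raise ValueError("bin_dt must be <= trajectory dt")
    n = len(trajectory)
    if focus_path is None:
        focus = np.broadcast_to(np.asarray(volume.center, float), (n, 3))
    else:
        focus = np.asarray(focus_path, dtype=float)
        if focus.shape != (n, 3):
            raise ValueError("focus_path must align with trajectory samples")

    rng = np.random.default_rng(seed)
    per_sample = max(1, int(round(traj_dt / bin_dt)))
    g = excitation_factor(trajectory.positions - focus, volume)
    gate = _photophysics_gate(trajectory.times, emitter, rng)
    rate = emitter.peak_rate * g * gate + emitter.background_rate
    # expand each trajectory sample into per_sample bins of width bin_dt
    lam = np.repeat(rate, per_sample) * bin_dt
    counts = rng.poisson(lam)
    times = (np.arange(lam.size) + 0.5) * bin_dt + trajectory.times[0]
    if scan_index is None:
        sidx = np.full(lam.size, -1, dtype=int)
    else:
        sidx = np.repeat(np.asarray(scan_index, dtype=int), per_sample)
    wavelengths = None
    if draw_wavelengths:
        wavelengths = np.full(lam.size, np.nan)
        nz = counts > 0
        if nz.any():
            wavelengths[nz] = emitter.spectrum.sample(times[nz], rng)
    return PhotonStream(times, sidx, counts, wavelengths, bin_dt=bin_dt)
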