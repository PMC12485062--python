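"""Active-feedback target locking: scanned focus, deviation estimation, piezo loop.

The simulated instrument scans the excitation focus over a small lateral
grid (electro-optic deflectors) while the axial focus oscillates
sinusoidally (TAG lens). Photon counts collected at each scan offset are
turned into an estimate of the emitter's deviation from the volume center
once per feedback period, and the stage is commanded to cancel it through a
first-order lag — keeping a diffusing emitter locked at the focus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .particle import (
    EmitterModel,
    ExcitationVolume,
    PhotonStream,
    Trajectory3D,
    excitation_factor,
)

__all__ = [
    "ScanPattern",
    "FeedbackConfig",
    "TrackingRecord",
    "InsufficientPhotonsError",
    "make_scan_pattern",
    "estimate_deviation",
    "run_tracking",
    "tracking_error_stats",
]

logger = logging.getLogger(__name__)


class InsufficientPhotonsError(RuntimeError):
    """Raised when a feedback update has too few photons to estimate from."""


@dataclass(frozen=True)
class ScanPattern:
    """Cyclic lateral offsets plus sinusoidal axial modulation.

    ``xy_offsets`` (n, 2) um are visited in order, one dwell each; the axial
    offset at absolute time t is ``z_amplitude * sin(2*pi*z_frequency*t)``.
    """

    xy_offsets: np.ndarray
    z_amplitude: float = 0.5
    z_frequency: float = 68.317e3
    dwell_per_point: float = 40e-6

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy_offsets, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy_offsets must have shape (n, 2)")
        if self.dwell_per_point <= 0:
            raise ValueError("dwell_per_point must be > 0")
        if not np.allclose(xy.mean(axis=0), 0.0, atol=1e-12):
            raise ValueError("xy grid must be centered on (0, 0)")
        object.__setattr__(self, "xy_offsets", xy)

    @property
    def n_points(self) -> int:
        return self.xy_offsets.shape[0]

    @property
    def period(self) -> float:
        return self.n_points * self.dwell_per_point

    def z_offset(self, t: np.ndarray) -> np.ndarray:
        return self.z_amplitude * np.sin(2 * np.pi * self.z_frequency * np.asarray(t))


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback-loop parameters.

    period        — deviation-estimate cadence, s (>= one full scan cycle)
    gain          — fraction of the estimated deviation commanded per update
    stage_time_constant — first-order lag of the piezo stage, s
    estimator     — 'centroid' (photon-weighted) or 'max_likelihood'
    """

    period: float = 1e-3
    gain: float = 1.0
    stage_time_constant: float = 2e-3
    estimator: str = "centroid"
    min_photons_per_update: int = 10
    escape_radius: float | None = None  # default 3 * waist_xy
    escape_grace: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.gain <= 1.0):
            raise ValueError("gain must be in [0, 1]")
        if self.period <= 0:
            raise ValueError("period must be > 0")


@dataclass(frozen=True)
class TrackingRecord:
    """Synchronized per-update series from a tracking run (times in s, um)."""

    times: np.ndarray
    true_position: np.ndarray
    stage_position: np.ndarray
    estimated_deviation: np.ndarray
    counts_per_update: np.ndarray
    locked: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.times).size
        for name in ("true_position", "stage_position", "estimated_deviation",
                     "counts_per_update", "locked"):
            if np.asarray(getattr(self, name)).shape[0] != n:
                raise ValueError(f"{name} length mismatch")

    def __len__(self) -> int:
        return self.times.size


def _is_non_adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1])) >= 2


def make_scan_pattern(
    grid_size: int = 5,
    grid_pitch: float = 0.25,
    z_amplitude: float = 0.5,
    z_frequency: float = 68.317e3,
    dwell_per_point: float = 40e-6,
) -> ScanPattern:
    """Build a centered square scan grid with a non-adjacent visiting order.

    Consecutive visited points are kept non-adjacent on the lattice (a
    knight's-tour-like ordering) so that residual stage motion between
    dwells does not correlate neighbouring samples. When no such ordering
    exists (e.g. 3x3, whose center neighbours every other point) the order
    falls back to a plain row scan with a logged warning.
    """
    if grid_size % 2 == 0:
        raise ValueError("grid_size must be odd")
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    if grid_pitch <= 0:
        raise ValueError("grid_pitch must be > 0")
    half = grid_size // 2
    lattice = [(i, j) for i in range(-half, half + 1) for j in range(-half, half + 1)]

    def greedy_tour() -> list[tuple[int, int]] | None:
        # most-constrained-first greedy; adequate for the small grids used
        for start in lattice:
            tour = [start]
            remaining = set(lattice) - {start}
            while remaining:
                cands = [p for p in remaining if _is_non_adjacent(p, tour[-1])]
                if not cands:
                    break
                # prefer the candidate with fewest onward non-adjacent options
                cands.sort(key=lambda p: (
                    sum(1 for q in remaining if q != p and _is_non_adjacent(q, p)), p))
                nxt = cands[0]
                tour.append(nxt)
                remaining.discard(nxt)
            if not remaining:
                return tour
        return None

    order = greedy_tour()
    if order is None:
        logger.warning(
            "no non-adjacent tour exists for %dx%d grid; using row-scan order",
            grid_size, grid_size)
        order = lattice
    xy = np.asarray(order, dtype=float) * grid_pitch
    return ScanPattern(xy, z_amplitude=z_amplitude, z_frequency=z_frequency,
                       dwell_per_point=dwell_per_point)


def estimate_deviation(
    counts: np.ndarray,
    scan: ScanPattern,
    volume: ExcitationVolume,
    estimator: str = "centroid",
    *,
    sample_offsets: np.ndarray | None = None,
    background_per_sample: float = 0.0,
    min_photons: int = 10,
    relative_background: float = 1e-3,
) -> np.ndarray:
    """Estimate the emitter's 3D deviation from the volume center.

    ``counts`` holds photon counts per scan sample within one feedback
    period. By default one count per lateral grid point is assumed (axial
    deviation 0); pass ``sample_offsets`` (n, 3) for full 3D samples that
    include the instantaneous TAG axial offset.

    centroid: background-corrected photon-weighted mean of the sample
    offsets, ``sum(n_i s_i) / sum(n_i)``.
    max_likelihood: maximizes ``sum(n_i log(G(s_i - d) + beta))`` over d by
    a coarse grid search refined with Nelder–Mead.
    """
    counts = np.asarray(counts, dtype=float)
    if sample_offsets is None:
        if counts.size != scan.n_points:
            raise ValueError("counts length must equal number of scan points")
        sample_offsets = np.column_stack([scan.xy_offsets, np.zeros(scan.n_points)])
    else:
        sample_offsets = np.asarray(sample_offsets, dtype=float)
        if sample_offsets.shape != (counts.size, 3):
            raise ValueError("sample_offsets must have shape (len(counts), 3)")

    corrected = np.clip(counts - background_per_sample, 0.0, None)
    total = corrected.sum()
    if total < min_photons:
        raise InsufficientPhotonsError(
            f"{total:.0f} background-corrected photons < min {min_photons}")

    centroid = (corrected[:, None] * sample_offsets).sum(axis=0) / total
    if estimator == "centroid":
        return centroid
    if estimator != "max_likelihood":
        raise ValueError(f"unknown estimator {estimator!r}")

    n_total = counts.sum()

    def nll(delta: np.ndarray) -> float:
        # multinomial likelihood of the photon split across scan samples;
        # the normalization term matters on a finite, unevenly covered grid
        g = excitation_factor(sample_offsets - delta, volume) + relative_background
        return -float(np.dot(counts, np.log(g)) - n_total * np.log(g.sum()))

    # coarse grid seeded at the centroid, then simplex refinement
    span = max(np.abs(sample_offsets).max(), volume.waist_xy)
    grid = np.linspace(-span, span, 7)
    best, best_val = centroid, nll(centroid)
    for dx in grid:
        for dy in grid:
            for dz in (grid if scan.z_amplitude > 0 else [0.0]):
                v = nll(np.array([dx, dy, dz]))
                if v < best_val:
                    best, best_val = np.array([dx, dy, dz]), v
    res = minimize(nll, best, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 500})
    # the estimate is only meaningful within the scanned region
    lo = sample_offsets.min(axis=0) - volume.waist_xy
    hi = sample_offsets.max(axis=0) + volume.waist_xy
    return np.clip(res.x, lo, hi)


def _as_positions(motion, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Positions (n, 3) of a source on ``times`` for the supported motion kinds."""
    if isinstance(motion, Trajectory3D):
        out = np.empty((times.size, 3))
        for k in range(3):
            out[:, k] = np.interp(times, motion.times, motion.positions[:, k])
        return out
    pos = np.asarray(motion, dtype=float)
    if pos.shape == (3,):  # static emitter
        return np.broadcast_to(pos, (times.size, 3)).copy()
    raise TypeError("motion must be a Trajectory3D, a D value, or a 3-vector")


def run_tracking(
    motion,
    emitter: EmitterModel,
    scan: ScanPattern,
    feedback: FeedbackConfig,
    duration: float,
    seed: int,
    feedback_enabled: bool = True,
    volume: ExcitationVolume | None = None,
    physics_dt: float = 1e-5,
    companions: list | None = None,
    draw_wavelengths: bool = False,
) -> tuple[TrackingRecord, PhotonStream]:
    """Run the closed-loop tracking event loop.

    ``motion`` is a diffusion coefficient (um^2/s, Brownian motion generated
    online), a static 3-position, or a pre-computed :class:`Trajectory3D`.
    ``companions`` optionally adds extra (motion, EmitterModel) sources in
    the same volume; the deviation estimate then responds to the combined
    emission (the loop tends to settle on the brighter source).

    Returns the per-update :class:`TrackingRecord` — whose
    ``stage_position`` series is the instrument's recorded trajectory — and
    the per-physics-bin :class:`PhotonStream`.
    """
    if duration <= feedback.period:
        raise ValueError("duration must exceed the feedback period")
    volume = volume or ExcitationVolume()
    rng = np.random.default_rng(seed)
    escape_radius = feedback.escape_radius or 3.0 * volume.waist_xy

    steps_per_dwell = max(1, int(round(scan.dwell_per_point / physics_dt)))
    dt = scan.dwell_per_point / steps_per_dwell
    steps_per_period = max(1, int(round(feedback.period / dt)))
    if feedback.period < scan.period * (1 - 1e-9):
        raise ValueError("feedback period must cover at least one scan cycle")
    n_periods = int(duration / feedback.period)

    # per-period template of scan indices (xy) within the period
    step_idx = np.arange(steps_per_period)
    xy_index_tpl = (step_idx // steps_per_dwell) % scan.n_points
    xy_tpl = scan.xy_offsets[xy_index_tpl]

    online = isinstance(motion, (int, float))
    sigma = np.sqrt(2.0 * float(motion) * dt) if online else 0.0
    emitter_pos = np.zeros(3)
    sources = [(motion, emitter)]
    if companions:
        sources += list(companions)
    comp_pos = [np.asarray(m, dtype=float) if not isinstance(m, Trajectory3D) else m
                for m, _ in sources[1:]]

    stage = np.zeros(3)
    command = np.zeros(3)
    alpha = 1.0 - np.exp(-dt / feedback.stage_time_constant)
    bg_per_sample = emitter.background_rate * dt

    times_out = np.empty(n_periods)
    true_out = np.empty((n_periods, 3))
    stage_out = np.empty((n_periods, 3))
    dev_out = np.zeros((n_periods, 3))
    counts_out = np.zeros(n_periods, dtype=int)
    locked_out = np.ones(n_periods, dtype=bool)

    all_counts = []
    all_times = []
    all_sidx = []
    unlock_since = None
    end_period = n_periods

    for p in range(n_periods):
        t0 = p * feedback.period
        t = t0 + (step_idx + 0.5) * dt
        z_tpl = scan.z_offset(t)

        # emitter motion over the period
        if online:
            if sigma > 0:
                incr = rng.normal(0.0, sigma, size=(steps_per_period, 3))
                pos = emitter_pos + np.cumsum(incr, axis=0)
            else:
                pos = np.broadcast_to(emitter_pos, (steps_per_period, 3)).copy()
            emitter_pos = pos[-1].copy()
        else:
            pos = _as_positions(motion, t, rng)
            emitter_pos = pos[-1]

        # stage relaxes toward the command through the first-order lag
        rel = command - stage
        decay = (1 - alpha) ** np.arange(1, steps_per_period + 1)
        stage_path = command[None, :] - rel[None, :] * decay[:, None]
        stage = stage_path[-1].copy()

        focus = stage_path.copy()
        focus[:, 0] += xy_tpl[:, 0]
        focus[:, 1] += xy_tpl[:, 1]
        focus[:, 2] += z_tpl

        rate = emitter.peak_rate * excitation_factor(pos - focus, volume)
        for (m, em), cp in zip(sources[1:], comp_pos):
            cpos = _as_positions(cp, t, rng) if isinstance(cp, Trajectory3D) else cp
            rate = rate + em.peak_rate * excitation_factor(cpos - focus, volume)
        rate = rate + emitter.background_rate
        counts = rng.poisson(rate * dt)

        all_counts.append(counts)
        all_times.append(t)
        all_sidx.append(xy_index_tpl)

        offsets3 = np.column_stack([xy_tpl, z_tpl])
        try:
            dev = estimate_deviation(
                counts, scan, volume, feedback.estimator,
                sample_offsets=offsets3, background_per_sample=bg_per_sample,
                min_photons=feedback.min_photons_per_update)
        except InsufficientPhotonsError:
            dev = np.zeros(3)  # hold last stage position
        if feedback_enabled and feedback.gain > 0:
            command = stage + feedback.gain * dev

        times_out[p] = t0 + feedback.period
        true_out[p] = emitter_pos
        stage_out[p] = stage
        dev_out[p] = dev
        counts_out[p] = counts.sum()

        dist = np.linalg.norm(emitter_pos - stage)
        if dist > escape_radius:
            if unlock_since is None:
                unlock_since = times_out[p]
            locked_out[p] = False
            if times_out[p] - unlock_since >= feedback.escape_grace:
                end_period = p + 1
                break
        else:
            unlock_since = None

    sl = slice(0, end_period)
    record = TrackingRecord(times_out[sl], true_out[sl], stage_out[sl],
                            dev_out[sl], counts_out[sl], locked_out[sl])
    counts_arr = np.concatenate(all_counts)
    times_arr = np.concatenate(all_times)
    sidx_arr = np.concatenate(all_sidx)
    wavelengths = None
    if draw_wavelengths:
        wavelengths = np.full(counts_arr.size, np.nan)
        nz = counts_arr > 0
        if nz.any():
            wavelengths[nz] = emitter.spectrum.sample(times_arr[nz], rng)
    stream = PhotonStream(times_arr, sidx_arr, counts_arr, wavelengths, bin_dt=dt)
    return record, stream


def tracking_error_stats(record: TrackingRecord) -> dict:
    """Summarize tracking fidelity over the locked part of a run.

    Returns RMS of (true - stage) per axis over locked updates, the locked
    fraction, and the effective duration (time to escape, or total).
    """
    if len(record) == 0:
        raise ValueError("empty tracking record")
    locked = record.locked.astype(bool)
    err = record.true_position - record.stage_position
    if locked.any():
        rms = np.sqrt(np.mean(err[locked] ** 2, axis=0))
    else:
        rms = np.full(3, np.nan)
    duration = float(record.times[-1] - record.times[0] + np.diff(record.times).mean()) \
        if len(record) > 1 else float(record.times[-1])
    return {
        "rms_error_um": rms,
        "lock_fraction": float(locked.mean()),
        "duration_s": duration,
        "fully_locked": bool(locked.all()),
    }
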