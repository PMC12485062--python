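"""Physical and kinetic quantities from tracked trajectories and peak series.

Covers mean-square-displacement diffusion estimation, hydrodynamic sizing
via Stokes–Einstein, windowed speed and spectral-change-rate statistics,
spectral change-point (particle switching) detection, and saturating-
exponential onset kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann
from scipy.optimize import curve_fit

from .particle import Trajectory3D
from .tracking import TrackingRecord

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "KineticsSummary",
    "OnsetFit",
    "compute_msd",
    "fit_diffusion",
    "stokes_einstein_diameter",
    "stokes_einstein_diffusion",
    "interval_kinetics",
    "detect_switch",
    "fit_onset_curve",
]


@dataclass(frozen=True)
class MSDCurve:
    """Mean square displacement vs lag time (um^2 vs s), lag 0 included."""

    lags: np.ndarray
    msd: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (self.lags.size == self.msd.size == self.counts.size):
            raise ValueError("MSD arrays must share length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be ascending")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass(frozen=True)
class DiffusionFit:
    D: float                 # um^2/s
    intercept: float         # um^2 (absorbs localization noise)
    fit_range: tuple[int, int]
    stderr_D: float
    dimensionality: int = 3
    negative_D_warning: bool = False


@dataclass(frozen=True)
class KineticsSummary:
    """Per-window kinetics (speeds in um/min, spectral rate in nm/min)."""

    window_starts: np.ndarray
    vertical_speed: np.ndarray
    translational_speed: np.ndarray
    vertical_displacement: np.ndarray
    planar_displacement: np.ndarray
    spectral_rate: np.ndarray

    def aggregate(self) -> dict:
        def ms(x):
            x = x[np.isfinite(x)]
            if x.size == 0:
                return (np.nan, np.nan)
            sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
            return (float(np.mean(x)), sem)

        return {
            "vertical_speed_um_per_min": ms(self.vertical_speed),
            "translational_speed_um_per_min": ms(self.translational_speed),
            "vertical_displacement_um": ms(self.vertical_displacement),
            "planar_displacement_um": ms(self.planar_displacement),
            "spectral_rate_nm_per_min": ms(self.spectral_rate),
        }


@dataclass(frozen=True)
class OnsetFit:
    """Fit of cumulative onset probability y = a * (1 - exp(-b x))."""

    a: float
    b: float
    half_time: float | None

    def __call__(self, x):
        return self.a * (1.0 - np.exp(-self.b * np.asarray(x, dtype=float)))


def compute_msd(trajectory: Trajectory3D, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs.

    MSD(k dt) = mean_i ||r_{i+k} - r_i||^2 for k = 0 .. max_lag_fraction*n.
    Requires uniform sampling.
    """
    n = len(trajectory)
    if n < 20:
        raise ValueError("need >= 20 trajectory points")
    dts = np.diff(trajectory.times)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("trajectory must be uniformly sampled")
    dt = float(dts[0])
    max_lag = max(1, int(max_lag_fraction * n))
    pos = trajectory.positions
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = n
    for k in range(1, max_lag + 1):
        d = pos[k:] - pos[:-k]
        msd[k] = np.mean(np.sum(d * d, axis=1))
        counts[k] = n - k
    return MSDCurve(lags * dt, msd, counts)


def fit_diffusion(
    msd: MSDCurve,
    dimensionality: int = 3,
    fit_lags: tuple[int, int] = (1, 10),
) -> DiffusionFit:
    """Weighted linear fit MSD = 2*dim*D*tau + c over the chosen lag range.

    Weights are the pair counts per lag; the intercept absorbs static
    localization noise. A negative fitted D is returned with a warning
    flag rather than raised.
    """
    if dimensionality not in (1, 2, 3):
        raise ValueError("dimensionality must be 1, 2 or 3")
    lo, hi = fit_lags
    hi = min(hi, msd.lags.size - 1)
    if lo < 1 or hi < lo:
        raise ValueError("invalid fit lag range")
    tau = msd.lags[lo:hi + 1]
    y = msd.msd[lo:hi + 1]
    w = msd.counts[lo:hi + 1].astype(float)
    W = np.diag(w)
    X = np.column_stack([tau, np.ones_like(tau)])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
    slope, intercept = float(beta[0]), float(beta[1])
    resid = y - X @ beta
    dof = max(tau.size - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(X.T @ W @ X)
    D = slope / (2.0 * dimensionality)
    stderr = float(np.sqrt(cov[0, 0])) / (2.0 * dimensionality)
    return DiffusionFit(D, intercept, (lo, hi), stderr, dimensionality,
                        negative_D_warning=D < 0)


def stokes_einstein_diameter(D: float, temperature: float, viscosity: float) -> float:
    """Hydrodynamic diameter d = k_B T / (3 pi eta D), in nm.

    D in um^2/s, temperature in K, viscosity in Pa s.
    """
    if D <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("all inputs must be > 0")
    D_si = D * 1e-12  # um^2/s -> m^2/s
    d_m = Boltzmann * temperature / (3.0 * np.pi * viscosity * D_si)
    return d_m * 1e9


def stokes_einstein_diffusion(diameter_nm: float, temperature: float,
                              viscosity: float) -> float:
    """Inverse relation: D (um^2/s) for a given hydrodynamic diameter (nm)."""
    if diameter_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("all inputs must be > 0")
    d_m = diameter_nm * 1e-9
    D_si = Boltzmann * temperature / (3.0 * np.pi * viscosity * d_m)
    return D_si * 1e12


def interval_kinetics(
    record: TrackingRecord,
    peak_series: np.ndarray | None = None,
    window: float = 60.0,
) -> KineticsSummary:
    """Windowed speeds and spectral change rates from a tracking record.

    Per non-overlapping window of length ``window`` seconds (on the stage
    trajectory, the instrument's recorded position):
      vertical speed      |z_end - z_start| / T        (um/min)
      translational speed ||(x,y)_end - (x,y)_start|| / T  (um/min)
      vertical displacement  z_end - z_start (signed, um)
      planar displacement    (x,y) displacement projected onto the first
                             window's planar motion direction (signed, um)
      spectral rate       slope of a linear fit of peak wavelength vs time
                          within the window (nm/min)
    ``peak_series`` is an (n, 2) array of (t_s, peak_nm) rows.
    """
    t = record.times
    span = float(t[-1] - t[0])
    if window > span:
        raise ValueError("window exceeds record duration")
    pos = record.stage_position
    starts, vs, ts_, vd, pd, sr = [], [], [], [], [], []
    ref_dir = None
    t0 = float(t[0])
    while t0 + window <= t[-1] + 1e-9:
        sel = (t >= t0 - 1e-12) & (t <= t0 + window + 1e-12)
        if sel.sum() < 2:
            t0 += window
            continue
        p = pos[sel]
        dt_min = window / 60.0
        dz = float(p[-1, 2] - p[0, 2])
        dxy = p[-1, :2] - p[0, :2]
        if ref_dir is None:
            nrm = np.linalg.norm(dxy)
            ref_dir = dxy / nrm if nrm > 0 else np.array([1.0, 0.0])
        starts.append(t0)
        vs.append(abs(dz) / dt_min)
        ts_.append(float(np.linalg.norm(dxy)) / dt_min)
        vd.append(dz)
        pd.append(float(dxy @ ref_dir))
        if peak_series is not None:
            ps = np.asarray(peak_series, dtype=float)
            psel = (ps[:, 0] >= t0 - 1e-12) & (ps[:, 0] <= t0 + window + 1e-12)
            if psel.sum() >= 2:
                slope = np.polyfit(ps[psel, 0], ps[psel, 1], 1)[0]
                sr.append(float(slope) * 60.0)  # nm/s -> nm/min
            else:
                sr.append(np.nan)
        else:
            sr.append(np.nan)
        t0 += window
    return KineticsSummary(np.asarray(starts), np.asarray(vs), np.asarray(ts_),
                           np.asarray(vd), np.asarray(pd), np.asarray(sr))


def detect_switch(
    peak_series: np.ndarray,
    min_jump: float = 5.0,
    window: int = 25,
) -> list[int]:
    """Detect abrupt peak-wavelength steps (particle switching events).

    A sliding two-window mean difference is computed at every index; an
    index is a change point when |mean(after) - mean(before)| exceeds
    max(min_jump, 3 * pooled rolling std). Detections closer than
    ``window`` samples are merged to the strongest. A slow drift whose
    per-window change stays below the threshold is not a switch.
    """
    ps = np.asarray(peak_series, dtype=float)
    lam = ps[:, 1] if ps.ndim == 2 else ps
    n = lam.size
    if n < 2 * window:
        raise ValueError("series must have length >= 2*window")
    diffs = np.zeros(n)
    thresh = np.zeros(n)
    for i in range(window, n - window + 1):
        a = lam[i - window:i]
        b = lam[i:i + window]
        diffs[i] = b.mean() - a.mean()
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        # std of the mean difference ~ pooled * sqrt(2/window)
        thresh[i] = max(min_jump, 3.0 * pooled * np.sqrt(2.0 / window))
    hits = np.where(np.abs(diffs) > thresh)[0]
    if hits.size == 0:
        return []
    merged: list[int] = []
    group = [hits[0]]
    for h in hits[1:]:
        if h - group[-1] <= window:
            group.append(h)
        else:
            merged.append(int(group[np.argmax(np.abs(diffs[group]))]))
            group = [h]
    merged.append(int(group[np.argmax(np.abs(diffs[group]))]))
    return merged


def fit_onset_curve(event_times: np.ndarray, observation_span: float,
                    n_total: int | None = None) -> OnsetFit:
    """Fit cumulative onset probability to y = a (1 - exp(-b x)).

    ``event_times`` are the onset times of the tracks that showed the
    event; ``n_total`` the number of tracks observed (defaults to the
    number of events, i.e. every track eventually converts). Events after
    ``observation_span`` are censored. The empirical cumulative fraction is
    evaluated on a uniform time grid over the observation span and fitted
    by nonlinear least squares. The half time solves y = 0.5:
    x = -ln(1 - 0.5/a)/b, defined only when a > 0.5.
    """
    et = np.sort(np.asarray(event_times, dtype=float))
    et = et[et <= observation_span]
    if et.size < 5:
        raise ValueError("need >= 5 events within the observation span")
    n_total = n_total or et.size
    x = np.linspace(0.0, observation_span, 200)
    y = np.searchsorted(et, x, side="right") / float(n_total)

    def model(x, a, b):
        return a * (1.0 - np.exp(-b * x))

    a0 = min(float(y[-1]), 1.0)
    b0 = 1.0 / max(float(np.median(et)), 1e-9)
    popt, _ = curve_fit(model, x, y, p0=[a0, b0],
                        bounds=([1e-6, 1e-12], [1.05, np.inf]), maxfev=10000)
    a, b = float(popt[0]), float(popt[1])
    half = -np.log(1.0 - 0.5 / a) / b if a > 0.5 else None
    return OnsetFit(a, b, half)
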