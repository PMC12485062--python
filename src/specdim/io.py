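"""Run configuration, file I/O, fixture generation and pipeline plumbing.

Conventions: all timestamps are seconds from acquisition start, positions
micrometers in the stage (lab) frame, wavelengths nanometers. Tabular data
is CSV, images are TIFF, configuration and sidecars are YAML. Every output
directory receives a sidecar recording the master seed and a hash of the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .calibration import CalibrationCurve, fit_dispersion, register_channels
from .camera import CameraConfig, DispersionModel, FramePair, frame_timing, render_frame_pair
from .particle import EmitterModel, ExcitationVolume, PhotonStream, SpectrumModel, Trajectory3D
from .tracking import FeedbackConfig, ScanPattern, TrackingRecord, make_scan_pattern, run_tracking

__all__ = [
    "RunConfig",
    "SyncIndex",
    "ConfigError",
    "load_config",
    "generate_fixture",
    "build_sync_index",
    "forward_fill_gaps",
    "calibrate_from_frames",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_tracking_csv",
    "read_tracking_csv",
    "write_photons_csv",
    "read_photons_csv",
    "write_frames",
    "read_frames",
    "write_calibration_yaml",
    "read_calibration_yaml",
    "write_reference_spectra_csv",
    "read_reference_spectra_csv",
]


class ConfigError(ValueError):
    """Configuration schema violation (unknown or invalid keys)."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MotionBlock(_Block):
    diffusion_um2_s: float = 2.67
    duration_s: float = 6.0
    drift_um_s: Optional[list[float]] = None


class SpectrumBlock(_Block):
    kind: str = "static_gaussian"
    peaks_nm: list[float] = Field(default_factory=lambda: [647.0])
    widths_nm: list[float] = Field(default_factory=lambda: [15.0])
    drift_rate_nm_s: float = 0.0
    step_time_s: float = 0.0
    component_weights: Optional[list[float]] = None


class EmitterBlock(_Block):
    peak_rate_hz: float = 1e6
    background_rate_hz: float = 1e3
    spectrum: SpectrumBlock = Field(default_factory=SpectrumBlock)


class TrackingBlock(_Block):
    grid_size: int = 5
    grid_pitch_um: float = 0.25
    z_amplitude_um: float = 0.5
    z_frequency_hz: float = 68.317e3
    dwell_per_point_s: float = 40e-6
    period_s: float = 1e-3
    gain: float = 1.0
    stage_time_constant_s: float = 2e-3
    estimator: str = "centroid"
    min_photons_per_update: int = 10
    waist_xy_um: float = 0.5
    waist_z_um: float = 1.0
    physics_dt_s: float = 1e-5
    feedback_enabled: bool = True


class CameraBlock(_Block):
    pixel_size_nm: float = 100.0
    frame_rows: int = 32
    frame_cols: int = 160
    exposure_s: float = 1e-3
    overhead_s: float = 1.5528e-3
    em_gain: float = 60.0
    read_noise_e: float = 3.0
    baseline_offset: float = 100.0
    split_fraction: float = 0.7


class CalibrationBlock(_Block):
    wavelengths_nm: list[float] = Field(
        default_factory=lambda: [470.0, 520.0, 570.0, 620.0, 670.0, 720.0])
    degree: int = 2
    photons_per_frame: int = 200000


class AnalysisBlock(_Block):
    stripe_row_halfwidth: int = 4
    qc_threshold_ratio: float = 2.0
    fit_error_cutoff: float = 0.3
    msd_fit_lags: list[int] = Field(default_factory=lambda: [1, 10])
    kinetics_window_s: float = 60.0


class UnmixingBlock(_Block):
    component_names: list[str] = Field(
        default_factory=lambda: ["mGold", "JF549", "LysoTracker"])
    component_peaks_nm: list[float] = Field(default_factory=lambda: [548.0, 580.0, 670.0])
    component_widths_nm: list[float] = Field(default_factory=lambda: [20.0, 30.0, 20.0])
    band_a_nm: list[float] = Field(default_factory=lambda: [500.0, 570.0])
    band_b_nm: list[float] = Field(default_factory=lambda: [570.0, 640.0])
    r_min: float = 0.2
    r_max: float = 2.5
    pka: float = 5.5


class ReconstructionBlock(_Block):
    voxel_pitch_um: float = 0.05
    normalize: str = "none"


class RunConfig(_Block):
    """Validated, schema-versioned run configuration (unknown keys rejected)."""

    schema_version: int = 1
    seed: int = 0
    motion: MotionBlock = Field(default_factory=MotionBlock)
    emitter: EmitterBlock = Field(default_factory=EmitterBlock)
    tracking: TrackingBlock = Field(default_factory=TrackingBlock)
    camera: CameraBlock = Field(default_factory=CameraBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    unmixing: UnmixingBlock = Field(default_factory=UnmixingBlock)
    reconstruction: ReconstructionBlock = Field(default_factory=ReconstructionBlock)

    # -- converters to domain objects ------------------------------------
    def spectrum_model(self) -> SpectrumModel:
        s = self.emitter.spectrum
        return SpectrumModel(kind=s.kind, peaks=tuple(s.peaks_nm),
                             widths=tuple(s.widths_nm),
                             drift_rate=s.drift_rate_nm_s, step_time=s.step_time_s,
                             component_weights=tuple(s.component_weights)
                             if s.component_weights else None)

    def emitter_model(self, weight_fn=None) -> EmitterModel:
        spec = self.spectrum_model()
        if weight_fn is not None:
            spec = SpectrumModel(kind="mixture", peaks=spec.peaks, widths=spec.widths,
                                 weight_fn=weight_fn)
        return EmitterModel(peak_rate=self.emitter.peak_rate_hz,
                            background_rate=self.emitter.background_rate_hz,
                            spectrum=spec)

    def scan_pattern(self) -> ScanPattern:
        t = self.tracking
        return make_scan_pattern(t.grid_size, t.grid_pitch_um, t.z_amplitude_um,
                                 t.z_frequency_hz, t.dwell_per_point_s)

    def feedback_config(self) -> FeedbackConfig:
        t = self.tracking
        return FeedbackConfig(period=t.period_s, gain=t.gain,
                              stage_time_constant=t.stage_time_constant_s,
                              estimator=t.estimator,
                              min_photons_per_update=t.min_photons_per_update)

    def excitation_volume(self) -> ExcitationVolume:
        return ExcitationVolume(self.tracking.waist_xy_um, self.tracking.waist_z_um)

    def camera_config(self) -> CameraConfig:
        c = self.camera
        return CameraConfig(pixel_size=c.pixel_size_nm,
                            frame_shape=(c.frame_rows, c.frame_cols),
                            exposure=c.exposure_s, overhead=c.overhead_s,
                            em_gain=c.em_gain, read_noise=c.read_noise_e,
                            baseline_offset=c.baseline_offset,
                            split_fraction=c.split_fraction)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**data)
    except Exception as exc:  # surface offending keys
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Presets: parameter sets for the two canonical demonstration scenarios.
# ---------------------------------------------------------------------------

def preset(name: str) -> RunConfig:
    """Named scenario presets.

    ``fig2`` — a single far-red fluorophore (static 647 nm peak) diffusing
    at 2.67 um^2/s, tracked for 6 s.
    ``fig3`` — a three-dye mixture whose pH-sensitive component fades after
    t = 40 s as the compartment acidifies (lysosome fusion scenario).
    """
    if name == "fig2":
        # 100 ms exposures, as used for single-fluorophore spectral tracking
        return RunConfig(motion=MotionBlock(diffusion_um2_s=2.67, duration_s=6.0),
                         emitter=EmitterBlock(peak_rate_hz=1e6,
                                              spectrum=SpectrumBlock(peaks_nm=[647.0])),
                         camera=CameraBlock(exposure_s=0.1))
    if name == "fig3":
        return RunConfig(
            motion=MotionBlock(diffusion_um2_s=0.05, duration_s=60.0),
            emitter=EmitterBlock(
                peak_rate_hz=5e5,
                spectrum=SpectrumBlock(kind="mixture",
                                       peaks_nm=[548.0, 580.0, 670.0],
                                       widths_nm=[20.0, 30.0, 20.0],
                                       component_weights=[0.35, 0.45, 0.2])),
            tracking=TrackingBlock(physics_dt_s=4e-5, period_s=2e-3),
            camera=CameraBlock(exposure_s=0.05),
        )
    raise ValueError(f"unknown preset {name!r}")


def fig3_ph_schedule(t: float, cal_rmin: float = 0.2, cal_rmax: float = 2.5,
                     pka: float = 5.5) -> float:
    """Scripted pH drop: neutral (7.0) until 40 s, then acidifying to 4.5."""
    if t < 40.0:
        return 7.0
    return max(4.5, 7.0 - 0.5 * (t - 40.0))


# ---------------------------------------------------------------------------
# CSV / TIFF / YAML writers and readers (round-trip stable)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def write_trajectory_csv(traj: Trajectory3D, path) -> None:
    df = pd.DataFrame({"t_s": traj.times, "x_um": traj.positions[:, 0],
                       "y_um": traj.positions[:, 1], "z_um": traj.positions[:, 2]})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> Trajectory3D:
    df = pd.read_csv(path)
    return Trajectory3D(df["t_s"].to_numpy(),
                        df[["x_um", "y_um", "z_um"]].to_numpy())


def write_tracking_csv(record: TrackingRecord, path) -> None:
    df = pd.DataFrame({
        "t_s": record.times,
        "x_true": record.true_position[:, 0], "y_true": record.true_position[:, 1],
        "z_true": record.true_position[:, 2],
        "x_stage": record.stage_position[:, 0], "y_stage": record.stage_position[:, 1],
        "z_stage": record.stage_position[:, 2],
        "dx_est": record.estimated_deviation[:, 0],
        "dy_est": record.estimated_deviation[:, 1],
        "dz_est": record.estimated_deviation[:, 2],
        "counts": record.counts_per_update,
        "locked": record.locked.astype(int),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracking_csv(path) -> TrackingRecord:
    df = pd.read_csv(path)
    return TrackingRecord(
        df["t_s"].to_numpy(),
        df[["x_true", "y_true", "z_true"]].to_numpy(),
        df[["x_stage", "y_stage", "z_stage"]].to_numpy(),
        df[["dx_est", "dy_est", "dz_est"]].to_numpy(),
        df["counts"].to_numpy(), df["locked"].to_numpy().astype(bool))


def write_photons_csv(stream: PhotonStream, path) -> None:
    df = pd.DataFrame({"t_s": stream.times, "scan_index": stream.scan_index,
                       "count": stream.counts})
    if stream.wavelengths is not None:
        df["wavelength_nm"] = stream.wavelengths
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_photons_csv(path, bin_dt: float = 0.0) -> PhotonStream:
    df = pd.read_csv(path)
    lam = df["wavelength_nm"].to_numpy() if "wavelength_nm" in df else None
    if bin_dt == 0.0 and len(df) > 1:
        bin_dt = float(np.median(np.diff(df["t_s"].to_numpy())))
    return PhotonStream(df["t_s"].to_numpy(), df["scan_index"].to_numpy(),
                        df["count"].to_numpy(), lam, bin_dt=bin_dt)


def write_frames(frames: list[FramePair], out_dir, stem: str = "fixture") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = np.stack([f.reference_image for f in frames])
    spec = np.stack([f.spectral_image for f in frames])
    paths = {"ref": out_dir / f"{stem}_ref.tif", "spec": out_dir / f"{stem}_spec.tif",
             "index": out_dir / f"{stem}_frames.csv"}
    tifffile.imwrite(paths["ref"], ref, photometric="minisblack")
    tifffile.imwrite(paths["spec"], spec, photometric="minisblack")
    pd.DataFrame({"frame": [f.frame_index for f in frames],
                  "timestamp_s": [f.timestamp for f in frames]}).to_csv(
        paths["index"], index=False, float_format=_FLOAT_FMT)
    return paths


def read_frames(out_dir, stem: str = "fixture",
                camera: CameraConfig | None = None) -> list[FramePair]:
    out_dir = Path(out_dir)
    ref = tifffile.imread(out_dir / f"{stem}_ref.tif")
    spec = tifffile.imread(out_dir / f"{stem}_spec.tif")
    idx = pd.read_csv(out_dir / f"{stem}_frames.csv")
    camera = camera or CameraConfig(frame_shape=ref.shape[1:])
    return [FramePair(ref[i], spec[i], timestamp=float(row.timestamp_s),
                      frame_index=int(row.frame), camera=camera)
            for i, row in enumerate(idx.itertuples())]


def write_calibration_yaml(curve: CalibrationCurve, path) -> None:
    data = {"calibration": {
        "coefficients": [float(c) for c in curve.dispersion.coefficients],
        "band_nm": [float(b) for b in curve.dispersion.band],
        "residual_rms_nm": curve.residual_rms_nm,
        "anchor_column": float(curve.anchor_column),
    }}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_calibration_yaml(path) -> CalibrationCurve:
    with open(path) as fh:
        data = yaml.safe_load(fh)["calibration"]
    model = DispersionModel(tuple(data["coefficients"]), tuple(data["band_nm"]))
    return CalibrationCurve(model, residuals_nm=np.array([]),
                            anchor_column=data["anchor_column"])


def write_reference_spectra_csv(ref, path) -> None:
    df = pd.DataFrame({"lambda_nm": ref.grid})
    for j, name in enumerate(ref.names):
        df[name] = ref.matrix[:, j]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_reference_spectra_csv(path):
    from .unmixing import ReferenceSpectra

    df = pd.read_csv(path)
    names = tuple(c for c in df.columns if c != "lambda_nm")
    return ReferenceSpectra(names, df[list(names)].to_numpy(),
                            df["lambda_nm"].to_numpy())


# ---------------------------------------------------------------------------
# Synchronization of camera frames with the tracking record
# ---------------------------------------------------------------------------


class SyncIndex:
    """Frame exposure windows mapped to tracking-record sample ranges."""

    def __init__(self, frame_windows: np.ndarray, sample_ranges: list[tuple[int, int]]):
        self.frame_windows = frame_windows
        self.sample_ranges = sample_ranges

    def __len__(self) -> int:
        return self.frame_windows.shape[0]


def build_sync_index(frame_timestamps: np.ndarray, exposure: float,
                     record: TrackingRecord, start_tolerance: float = 0.1) -> SyncIndex:
    """Map each frame's exposure window to the tracking samples it covers.

    ``frame_timestamps`` are exposure start times; windows are
    [t, t + exposure), non-overlapping and ordered. The two clocks must
    start within ``start_tolerance`` seconds.
    """
    ft = np.asarray(frame_timestamps, dtype=float)
    if np.any(np.diff(ft) <= 0):
        raise ValueError("frame timestamps must be strictly increasing")
    if np.any(np.diff(ft) < exposure - 1e-12):
        raise ValueError("frame windows overlap")
    if abs(ft[0] - record.times[0]) > start_tolerance:
        raise ValueError("frame and tracking clocks start too far apart")
    windows = np.column_stack([ft, ft + exposure])
    t = record.times
    # tracking samples are stamped at the END of each update period, so a
    # frame exposing over (w0, w1] covers the samples with w0 < t <= w1
    ranges = [(int(np.searchsorted(t, w0, side="right")),
               int(np.searchsorted(t, w1, side="right"))) for w0, w1 in windows]
    return SyncIndex(windows, ranges)


def forward_fill_gaps(values: np.ndarray, gap_mask: np.ndarray) -> np.ndarray:
    """Replace flagged gap frames with the last preceding valid value.

    Used for brief interruptions (e.g. brightfield checks) where the
    spectral value is carried forward from the previous point.
    """
    out = np.asarray(values, dtype=float).copy()
    gap = np.asarray(gap_mask, dtype=bool)
    last = np.nan
    for i in range(out.size):
        if gap[i]:
            out[i] = last
        else:
            last = out[i]
    return out


# ---------------------------------------------------------------------------
# Calibration and fixture generation
# ---------------------------------------------------------------------------


def calibrate_from_frames(camera: CameraConfig, dispersion: DispersionModel,
                          wavelengths: list[float], photons: int, seed: int,
                          degree: int = 2) -> CalibrationCurve:
    """Calibrate the wavelength<->pixel mapping from monochromatic frames.

    Renders one narrow-line frame per calibration wavelength, measures the
    reference-to-stripe column shift by center-of-mass registration, and
    fits the dispersion polynomial to the (wavelength, shift) points.
    """
    rng = np.random.default_rng(seed)
    points = []
    anchor = None
    for lam0 in wavelengths:
        sampler = lambda n, r, mu=lam0: r.normal(mu, 0.5, n)
        fp = render_frame_pair(np.zeros(2), sampler, photons, camera, dispersion, rng)
        shift_col, _ = register_channels(fp.reference_image, fp.spectral_image)
        points.append((lam0, shift_col))
        if anchor is None:
            from .calibration import _background_subtract, _center_of_mass

            bg, _, _ = _background_subtract(fp.reference_image)
            anchor = _center_of_mass(bg)[1]
    return fit_dispersion(points, degree=degree, band=dispersion.band,
                          anchor_column=anchor or 0.0)


def generate_fixture(config: RunConfig, out_dir, weight_fn=None) -> dict:
    """Run motion -> tracking -> camera end to end and write a fixture bundle.

    Writes the tracking record, photon stream, paired frame stacks,
    reference spectra, fitted calibration, and a ground-truth YAML
    (true diffusion coefficient, spectrum parameters, seed). Deterministic
    per seed: reruns produce byte-identical CSV outputs.
    """
    from .unmixing import gaussian_reference_spectra

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    s_track, s_cal, s_frames = rng.integers(0, 2**31 - 1, size=3)

    emitter = config.emitter_model(weight_fn=weight_fn)
    scan = config.scan_pattern()
    feedback = config.feedback_config()
    volume = config.excitation_volume()
    camera = config.camera_config()
    dispersion = DispersionModel()

    record, stream = run_tracking(
        config.motion.diffusion_um2_s, emitter, scan, feedback,
        duration=config.motion.duration_s, seed=int(s_track),
        feedback_enabled=config.tracking.feedback_enabled, volume=volume,
        physics_dt=config.tracking.physics_dt_s, draw_wavelengths=True)

    curve = calibrate_from_frames(camera, dispersion,
                                  config.calibration.wavelengths_nm,
                                  config.calibration.photons_per_frame,
                                  int(s_cal), config.calibration.degree)

    # render one frame pair per exposure window from the detected photons
    frame_period, _ = frame_timing(camera.exposure, camera)
    frng = np.random.default_rng(int(s_frames))
    frames = []
    t0 = 0.0
    i = 0
    t_end = record.times[-1]
    while t0 + camera.exposure <= t_end:
        sel = (stream.times >= t0) & (stream.times < t0 + camera.exposure)
        budget = int(stream.counts[sel].sum())
        tr = record.times
        j = min(np.searchsorted(tr, t0 + camera.exposure / 2), len(record) - 1)
        residual = record.true_position[j, :2] - record.stage_position[j, :2]
        tm = t0 + camera.exposure / 2
        sampler = lambda n, r, t=tm: emitter.spectrum.sample(np.full(n, t), r)
        frames.append(render_frame_pair(residual, sampler, budget, camera,
                                        dispersion, frng, timestamp=t0, frame_index=i))
        t0 += frame_period
        i += 1

    ref_spectra = gaussian_reference_spectra(
        np.arange(450.0, 750.5, 1.0),
        tuple(config.unmixing.component_names),
        tuple(config.unmixing.component_peaks_nm),
        tuple(config.unmixing.component_widths_nm))

    paths = {"tracking": out_dir / "tracking_record.csv",
             "photons": out_dir / "photons.csv",
             "calibration": out_dir / "calibration.yaml",
             "reference_spectra": out_dir / "reference_spectra.csv",
             "ground_truth": out_dir / "ground_truth.yaml",
             "sidecar": out_dir / "run_sidecar.yaml"}
    write_tracking_csv(record, paths["tracking"])
    write_photons_csv(stream, paths["photons"])
    write_calibration_yaml(curve, paths["calibration"])
    write_reference_spectra_csv(ref_spectra, paths["reference_spectra"])
    paths.update(write_frames(frames, out_dir))

    truth = {"diffusion_um2_s": config.motion.diffusion_um2_s,
             "spectrum": config.emitter.spectrum.model_dump(),
             "seed": config.seed}
    with open(paths["ground_truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    with open(paths["sidecar"], "w") as fh:
        yaml.safe_dump({"seed": config.seed, "config_hash": config.config_hash(),
                        "config": self_dump(config)}, fh, sort_keys=True)
    return {"record": record, "stream": stream, "frames": frames,
            "calibration": curve, "reference_spectra": ref_spectra, "paths": paths}


def self_dump(config: RunConfig) -> dict:
    return json.loads(json.dumps(config.model_dump()))
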