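"""3D volume reconstruction by registering photons to laser-focus positions.

Each detected photon is assigned the instantaneous focus position — the
stage position at its timestamp plus the active scan offset (lateral from
the scan grid index, axial from the TAG phase) — and binned into a voxel
grid. Overlaying the high-rate tracked trajectory on this volume gives the
multi-resolution product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .particle import PhotonStream
from .tracking import ScanPattern, TrackingRecord

__all__ = ["VolumeImage", "reconstruct_volume", "export_overlay", "focus_positions"]


@dataclass(frozen=True)
class VolumeImage:
    """Voxelized photon counts with grid geometry (um) and dwell times (s)."""

    origin: np.ndarray          # (3,) lower corner, um
    pitch: float                # voxel edge, um
    counts: np.ndarray          # (nx, ny, nz) photon counts
    dwell: np.ndarray           # (nx, ny, nz) seconds spent per voxel
    total_registered: int
    overflow: int = 0
    rate: np.ndarray | None = None  # counts / dwell when dwell-normalized

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.total_registered:
            raise ValueError("count conservation violated")


def focus_positions(photons: PhotonStream, record: TrackingRecord,
                    scan: ScanPattern) -> np.ndarray:
    """Instantaneous focus position (n, 3) for every photon bin.

    Stage position is interpolated at each photon time; the lateral scan
    offset comes from the recorded scan index, the axial offset from the
    TAG phase at the bin time.
    """
    t = np.asarray(photons.times, dtype=float)
    if t.min() < record.times.min() - 1.5e-3 or t.max() > record.times.max() + 1.5e-3:
        raise ValueError("photon timestamps extend outside the tracking record")
    stage = np.empty((t.size, 3))
    for k in range(3):
        stage[:, k] = np.interp(t, record.times, record.stage_position[:, k])
    idx = np.asarray(photons.scan_index, dtype=int)
    xy = np.where(idx[:, None] >= 0, scan.xy_offsets[np.clip(idx, 0, None)], 0.0)
    out = stage.copy()
    out[:, 0] += xy[:, 0]
    out[:, 1] += xy[:, 1]
    out[:, 2] += scan.z_offset(t)
    return out


def reconstruct_volume(
    photons: PhotonStream,
    record: TrackingRecord,
    scan: ScanPattern,
    voxel_pitch: float = 0.05,
    normalize: str = "none",
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VolumeImage:
    """Bin photons into voxels at their focus positions.

    The grid defaults to the stage excursion bounding box padded by the
    scan amplitudes. Photons falling outside the grid are tallied in the
    overflow counter so photon conservation holds exactly:
    sum(counts) + overflow == total photons. ``normalize='dwell'`` divides
    by per-voxel dwell time (the raw integer counts are kept alongside).
    """
    if normalize not in ("none", "dwell"):
        raise ValueError("normalize must be 'none' or 'dwell'")
    pos = focus_positions(photons, record, scan)
    counts = np.asarray(photons.counts, dtype=int)
    if origin is None or shape is None:
        margin = np.array([
            np.abs(scan.xy_offsets[:, 0]).max() + voxel_pitch,
            np.abs(scan.xy_offsets[:, 1]).max() + voxel_pitch,
            scan.z_amplitude + voxel_pitch,
        ])
        lo = record.stage_position.min(axis=0) - margin
        hi = record.stage_position.max(axis=0) + margin
        origin = lo
        shape = tuple(np.maximum(np.ceil((hi - lo) / voxel_pitch).astype(int), 1))
    origin = np.asarray(origin, dtype=float)

    idx = np.floor((pos - origin) / voxel_pitch).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    grid = np.zeros(shape, dtype=np.int64)
    dwell = np.zeros(shape, dtype=float)
    ii = idx[inside]
    np.add.at(grid, (ii[:, 0], ii[:, 1], ii[:, 2]), counts[inside])
    np.add.at(dwell, (ii[:, 0], ii[:, 1], ii[:, 2]), photons.bin_dt)
    overflow = int(counts[~inside].sum())
    rate = None
    if normalize == "dwell":
        rate = np.where(dwell > 0, grid / np.where(dwell > 0, dwell, 1.0), 0.0)
    return VolumeImage(origin, float(voxel_pitch), grid, dwell,
                       total_registered=int(grid.sum()), overflow=overflow,
                       rate=rate)


def export_overlay(volume: VolumeImage, record: TrackingRecord,
                   peak_series: np.ndarray | None, out_dir) -> dict:
    """Write sum-intensity projections and the spectrally annotated trajectory.

    Projections (xy, xz, yz) are exact sums of the voxel counts along the
    collapsed axis, written as TIFF; the trajectory CSV carries a
    ``peak_nm`` column interpolated from ``peak_series`` for spectral
    color-coding. Returns the projection arrays and written paths.
    """
    from pathlib import Path

    import pandas as pd
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    projections = {
        "xy": volume.counts.sum(axis=2),
        "xz": volume.counts.sum(axis=1),
        "yz": volume.counts.sum(axis=0),
    }
    paths = {}
    for name, proj in projections.items():
        p = out_dir / f"projection_{name}.tif"
        tifffile.imwrite(p, proj.astype(np.float32), photometric="minisblack")
        paths[name] = p

    df = pd.DataFrame({
        "t_s": record.times,
        "x_um": record.stage_position[:, 0],
        "y_um": record.stage_position[:, 1],
        "z_um": record.stage_position[:, 2],
    })
    if peak_series is not None:
        ps = np.asarray(peak_series, dtype=float)
        df["peak_nm"] = np.interp(record.times, ps[:, 0], ps[:, 1])
    traj_path = out_dir / "trajectory_overlay.csv"
    df.to_csv(traj_path, index=False)
    paths["trajectory"] = traj_path
    return {"projections": projections, "paths": paths}
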