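"""Volume and tabular I/O plus the serial-scan acquisition schedule.

CT volumes are exchanged as scalar NIfTI-1 images on an axis-aligned grid.
World coordinates are continuous, in millimetres; voxel indices are 0-based
and a voxel centre sits at ``origin + index * spacing``.

A monitored ablation is a fixed-table serial acquisition: one pre-ablation
scan at t = 0, upslope scans at a short interval ending at the time of peak
temperature, then post-ablation scans at a longer interval covering the
cooling phase.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

PHASES = ("pre", "upslope", "peak", "downslope")

#: Fill value for voxels that fall outside the field of view after resampling.
SENTINEL_HU = -32768.0


@dataclass
class VolumeScan:
    """One 3-D attenuation grid with its geometry and acquisition time.

    Parameters
    ----------
    grid:
        3-D array of attenuation values in Hounsfield units.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    time_s:
        Seconds since ablation power-on (the pre scan has ``time_s <= 0``).
    phase:
        One of ``pre``, ``upslope``, ``peak``, ``downslope``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    time_s: float = 0.0
    phase: str = "pre"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.grid.ndim}")
        if not np.all(np.isfinite(self.grid)):
            raise ValidationError("attenuation grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}, expected one of {PHASES}")
        if self.phase == "pre" and self.time_s > 0:
            raise ValidationError("pre-ablation scan must have time_s <= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of all voxel centres, one array per axis."""
        axes = [
            self.origin[a] + np.arange(self.grid.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def world_to_index(self, point: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a world point (mm)."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )


@dataclass
class ScanSeries:
    """Ordered serial scans of one ablation with the probe geometry."""

    ablation_id: str
    scans: list[VolumeScan]
    probe_tip: tuple[float, float, float]
    probe_axis: tuple[float, float, float]

    def __post_init__(self) -> None:
        times = [s.time_s for s in self.scans]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError("scan times must be strictly increasing")
        shapes = {s.grid.shape for s in self.scans}
        spacings = {s.spacing for s in self.scans}
        if len(shapes) > 1 or len(spacings) > 1:
            raise ValidationError("all scans in a series must share shape and spacing")
        n_peak = sum(s.phase == "peak" for s in self.scans)
        if n_peak != 1:
            raise ValidationError(f"series must contain exactly one peak scan, got {n_peak}")
        axis = np.asarray(self.probe_axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValidationError("probe_axis must have unit norm")
        self.probe_tip = tuple(float(c) for c in self.probe_tip)
        self.probe_axis = tuple(float(c) for c in axis)

    @property
    def peak(self) -> VolumeScan:
        return next(s for s in self.scans if s.phase == "peak")

    @property
    def pre(self) -> VolumeScan:
        return self.scans[0]


@dataclass
class TemperatureTrace:
    """Invasive fiberoptic temperature samples for one ablation.

    ``samples`` is a DataFrame with columns ``time_s``, ``sensor_id``,
    ``temperature_c``; per-sensor times are strictly increasing and all
    temperatures lie in [0, 150] °C.
    """

    ablation_id: str
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"time_s", "sensor_id", "temperature_c"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"trace is missing columns {sorted(missing)}")
        temps = self.samples["temperature_c"].to_numpy(dtype=float)
        if len(temps) and (temps.min() < 0 or temps.max() > 150):
            raise ValidationError("temperatures must lie within [0, 150] degC")
        for sensor, grp in self.samples.groupby("sensor_id"):
            t = grp["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"non-monotone times for sensor {sensor!r}")

    @property
    def sensor_ids(self) -> list[str]:
        return sorted(self.samples["sensor_id"].unique())

    def sensor(self, sensor_id: str) -> pd.DataFrame:
        return self.samples[self.samples["sensor_id"] == sensor_id].reset_index(drop=True)

    def max_temperature(self) -> float:
        return float(self.samples["temperature_c"].max())


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, time_s: float = 0.0, phase: str = "pre") -> VolumeScan:
    """Read a single scalar NIfTI volume into a :class:`VolumeScan`.

    Attenuation values are passed through unchanged; spacing and origin come
    from the header (axis-aligned affines only).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeScan(grid=np.asarray(data, dtype=np.float64), spacing=spacing,
                      origin=origin, time_s=time_s, phase=phase)


def write_volume(scan: VolumeScan, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeScan` as NIfTI-1 (float64, no intensity scaling)."""
    affine = np.diag(list(scan.spacing) + [1.0])
    affine[:3, 3] = scan.origin
    img = nib.Nifti1Image(scan.grid.astype(np.float64), affine)
    img.header.set_zooms(scan.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Acquisition schedule
# ---------------------------------------------------------------------------

def build_schedule(
    n_upslope: int = 10,
    upslope_interval_s: float = 30.0,
    n_post: int = 10,
    post_interval_s: float = 60.0,
) -> list[tuple[float, str]]:
    """Model the serial-scan protocol as ``(time_s, phase)`` entries.

    The first scan is the pre-ablation baseline at t = 0; upslope scans follow
    at ``upslope_interval_s``, the last of them labelled ``peak``; post-ablation
    (downslope) scans continue from the peak at ``post_interval_s``.  The
    default reproduces the monitoring protocol of ten 30-s upslope scans
    followed by ten 60-s post-ablation scans (20 scans per ablation).
    """
    if n_upslope < 2:
        raise ParameterError("n_upslope must be >= 2 (pre and peak cannot coincide)")
    if n_post < 0:
        raise ParameterError("n_post must be >= 0")
    if upslope_interval_s <= 0 or post_interval_s <= 0:
        raise ParameterError("scan intervals must be positive")
    schedule: list[tuple[float, str]] = [(0.0, "pre")]
    for k in range(1, n_upslope):
        phase = "peak" if k == n_upslope - 1 else "upslope"
        schedule.append((k * float(upslope_interval_s), phase))
    t_peak = schedule[-1][0]
    for k in range(1, n_post + 1):
        schedule.append((t_peak + k * float(post_interval_s), "downslope"))
    return schedule


# ---------------------------------------------------------------------------
# Temperature traces
# ---------------------------------------------------------------------------

def read_temperature_trace(path: str | os.PathLike, ablation_id: str = "") -> TemperatureTrace:
    """Read a trace CSV with columns ``time_s,sensor_id,temperature_c``."""
    df = pd.read_csv(path)
    required = {"time_s", "sensor_id", "temperature_c"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    return TemperatureTrace(ablation_id=ablation_id or os.path.basename(str(path)), samples=df)


def write_temperature_trace(trace: TemperatureTrace, path: str | os.PathLike) -> None:
    trace.samples.to_csv(path, index=False, float_format="%.6f")
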