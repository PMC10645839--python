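"""Synthetic ablation-phantom generator.

Emulates a heated liver volume monitored by serial CT: tissue attenuation
falls linearly with temperature (negative HU/°C slope), the probe is a
hyperdense cylinder, gas forms as hypodense blobs near the tip during the
heating phase, scans carry additive Gaussian noise and, optionally, small
inter-scan rigid shifts.

The heat model is an explicit stand-in — a radial Gaussian around the probe
whose amplitude ramps linearly to the peak over the upslope and decays
exponentially afterwards — chosen because its isotherm radii have closed
forms, so segmentation accuracy can be checked analytically:

    T(x, t) = T_core + A(t) * exp(-d(x)^2 / (2 * sigma(t)^2))

with d(x) the distance from the probe segment, A ramping 0 → peak_delta_t_c
over [0, t_peak] then halving once per post-ablation interval, and sigma
growing linearly from sigma_peak/2 to sigma_peak over the upslope.  The
ground-truth necrosis zone is the region whose *cumulative maximum*
temperature reached 70 °C, so later cooling never shrinks it.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ValidationError
from .io_volumes import (
    ScanSeries,
    TemperatureTrace,
    VolumeScan,
    build_schedule,
    write_temperature_trace,
    write_volume,
)

NECROSIS_TEMP_C = 70.0


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the synthetic ablation, with protocol-matched defaults.

    Geometry is axis-aligned: the probe runs along ``probe_axis`` (default +z)
    and ends at ``probe_tip`` (default: grid centre).  ``true_slope`` is the
    HU-per-°C attenuation sensitivity the generator bakes into every scan;
    the analysis is supposed to recover it.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    baseline_hu: float = 55.0
    true_slope: float = -1.96
    core_temp_c: float = 37.0
    peak_delta_t_c: float = 60.0
    sigma_mm_at_peak: float = 10.0
    noise_sd_hu: float = 8.0
    probe_tip: tuple[float, float, float] | None = None
    probe_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    probe_radius_mm: float = 1.0
    probe_length_mm: float = 60.0
    probe_hu: float = 3000.0
    gas_enabled: bool = True
    gas_hu: float = -700.0
    gas_max_radius_mm: float = 8.0
    motion_sd_mm: float = 0.0
    # serial-scan protocol: 10 upslope scans every 30 s, 10 post scans every 60 s
    n_upslope: int = 10
    upslope_interval_s: float = 30.0
    n_post: int = 10
    post_interval_s: float = 60.0
    sensor_offsets_mm: tuple[float, ...] = (5.0, 10.0)
    ablation_id: str = "phantom-A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_slope >= 0:
            raise ParameterError("true_slope must be negative (heating lowers HU)")
        if self.peak_delta_t_c <= 0:
            raise ParameterError("peak_delta_t_c must be positive")
        if self.noise_sd_hu < 0 or self.motion_sd_mm < 0:
            raise ParameterError("noise/motion standard deviations must be >= 0")
        if self.sigma_mm_at_peak <= 0:
            raise ParameterError("sigma_mm_at_peak must be positive")

    @property
    def tip(self) -> np.ndarray:
        if self.probe_tip is not None:
            return np.asarray(self.probe_tip, dtype=float)
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    @property
    def axis(self) -> np.ndarray:
        a = np.asarray(self.probe_axis, dtype=float)
        return a / np.linalg.norm(a)

    @property
    def t_peak_s(self) -> float:
        return (self.n_upslope - 1) * self.upslope_interval_s

    @property
    def t_end_s(self) -> float:
        return self.t_peak_s + self.n_post * self.post_interval_s

    def schedule(self) -> list[tuple[float, str]]:
        return build_schedule(self.n_upslope, self.upslope_interval_s,
                              self.n_post, self.post_interval_s)

    def sensor_positions(self) -> np.ndarray:
        """Sensors sit parallel to the probe, laterally offset in the tip plane."""
        perp = _perpendicular(self.axis)
        return np.stack([self.tip + off * perp for off in self.sensor_offsets_mm])


@dataclass
class GroundTruth:
    """Per-scan true temperature fields and the necrosis mask.

    ``temperature_fields`` are in the motion-free tissue frame;
    ``applied_shifts`` records each scan's rigid translation (mm) so
    registration accuracy can be scored against it.
    """

    temperature_fields: list[np.ndarray] = field(repr=False)
    necrosis_mask: np.ndarray = field(repr=False)
    applied_shifts: np.ndarray
    sensor_positions: np.ndarray


def _perpendicular(axis: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``axis``."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - np.dot(trial, axis) * axis
    return perp / np.linalg.norm(perp)


def _segment_distance(points: np.ndarray, tip: np.ndarray, axis: np.ndarray,
                      length: float) -> np.ndarray:
    """Distance (mm) from each point to the probe segment ending at the tip."""
    rel = points - tip
    s = rel @ axis  # axial coordinate, 0 at tip, negative along the shaft
    s_clamped = np.clip(s, -length, 0.0)
    closest = tip + s_clamped[..., None] * axis
    return np.linalg.norm(points - closest, axis=-1)


def _amplitude(cfg: PhantomConfig, time_s: float) -> float:
    if time_s <= cfg.t_peak_s:
        return cfg.peak_delta_t_c * time_s / cfg.t_peak_s
    # exponential cooling, half-life of one post-ablation interval
    return cfg.peak_delta_t_c * 0.5 ** ((time_s - cfg.t_peak_s) / cfg.post_interval_s)


def _sigma(cfg: PhantomConfig, time_s: float) -> float:
    if time_s <= cfg.t_peak_s:
        frac = time_s / cfg.t_peak_s
        return cfg.sigma_mm_at_peak * (0.5 + 0.5 * frac)
    return cfg.sigma_mm_at_peak


def _world_points(cfg: PhantomConfig) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(cfg.shape, cfg.spacing)]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack(grids, axis=-1)


def temperature_at(cfg: PhantomConfig, points: np.ndarray, time_s: float) -> np.ndarray:
    """Analytic temperature (°C) at arbitrary world points."""
    if time_s < 0:
        raise ParameterError("time_s must be >= 0")
    d = _segment_distance(points, cfg.tip, cfg.axis, cfg.probe_length_mm)
    a = _amplitude(cfg, time_s)
    sig = _sigma(cfg, time_s)
    return cfg.core_temp_c + a * np.exp(-(d ** 2) / (2.0 * sig ** 2))


def temperature_field(cfg: PhantomConfig, time_s: float) -> np.ndarray:
    """True 3-D temperature field (°C) at ``time_s`` on the phantom grid."""
    if time_s < 0:
        raise ParameterError("time_s must be >= 0")
    if time_s > cfg.t_end_s:
        raise ParameterError(f"time_s={time_s} beyond schedule end {cfg.t_end_s}")
    return temperature_at(cfg, _world_points(cfg), time_s)


def analytic_isotherm_radius(cfg: PhantomConfig, temp_c: float = NECROSIS_TEMP_C,
                             time_s: float | None = None) -> float:
    """Closed-form radius (mm) of the ``temp_c`` isotherm around the probe.

    Inverts the Gaussian profile at the given time (default: peak).  Returns
    0 if the isotherm is never reached.
    """
    t = cfg.t_peak_s if time_s is None else time_s
    a = _amplitude(cfg, t)
    rise = temp_c - cfg.core_temp_c
    if rise <= 0:
        raise ParameterError("isotherm temperature must exceed the core temperature")
    if rise >= a:
        return 0.0
    return _sigma(cfg, t) * np.sqrt(2.0 * np.log(a / rise))


def _child_rng(seed: int, scan_index: int, stream: str) -> np.random.Generator:
    """Deterministic per-scan, per-purpose RNG derived from the root seed."""
    digest = hashlib.sha256(f"{seed}/{scan_index}/{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def synthesize_series(
    cfg: PhantomConfig,
    schedule: list[tuple[float, str]] | None = None,
) -> tuple[ScanSeries, TemperatureTrace, GroundTruth]:
    """Generate the full serial-CT dataset for one synthetic ablation.

    Each scan is ``baseline_hu + true_slope * (T - core) + noise`` with probe
    voxels overwritten by ``probe_hu`` and, on heating-phase scans, hypodense
    gas blobs within ``gas_max_radius_mm`` of the tip.  A per-scan rigid shift
    (SD ``motion_sd_mm``) moves the whole anatomy relative to the scanner grid
    and is recorded in the ground truth.  Everything is a pure function of
    ``cfg.seed``.
    """
    if schedule is None:
        schedule = cfg.schedule()
    points0 = _world_points(cfg)
    scans: list[VolumeScan] = []
    fields: list[np.ndarray] = []
    shifts = np.zeros((len(schedule), 3))
    sensors = cfg.sensor_positions()
    trace_rows: list[dict] = []

    for k, (time_s, phase) in enumerate(schedule):
        if cfg.motion_sd_mm > 0:
            shifts[k] = _child_rng(cfg.seed, k, "motion").normal(0.0, cfg.motion_sd_mm, 3)
        # anatomy shifted by +s appears at scanner coordinate x as tissue(x - s)
        tissue_pts = points0 - shifts[k]
        t_true = temperature_at(cfg, points0, time_s)  # motion-free tissue frame
        t_seen = temperature_at(cfg, tissue_pts, time_s) if cfg.motion_sd_mm > 0 else t_true
        grid = cfg.baseline_hu + cfg.true_slope * (t_seen - cfg.core_temp_c)
        if cfg.noise_sd_hu > 0:
            grid = grid + _child_rng(cfg.seed, k, "noise").normal(
                0.0, cfg.noise_sd_hu, cfg.shape
            )
        # partial-volume edge width: objects blend linearly over ~one voxel,
        # so their apparent edges encode subvoxel position as on a real scanner
        pv_mm = float(np.mean(cfg.spacing))
        if cfg.gas_enabled and phase in ("upslope", "peak"):
            rng = _child_rng(cfg.seed, k, "gas")
            for _ in range(int(rng.integers(1, 4))):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                centre = cfg.tip + direction * cfg.gas_max_radius_mm * rng.random() ** (1 / 3)
                radius = rng.uniform(1.0, 2.5)
                d_gas = np.linalg.norm(tissue_pts - centre, axis=-1)
                frac = np.clip((radius + pv_mm / 2 - d_gas) / pv_mm, 0.0, 1.0)
                grid = (1 - frac) * grid + frac * cfg.gas_hu
        if cfg.probe_radius_mm > 0:
            d_probe = _segment_distance(tissue_pts, cfg.tip, cfg.axis, cfg.probe_length_mm)
            frac = np.clip((cfg.probe_radius_mm + pv_mm / 2 - d_probe) / pv_mm, 0.0, 1.0)
            grid = (1 - frac) * grid + frac * cfg.probe_hu
        scans.append(VolumeScan(grid=grid, spacing=cfg.spacing, origin=(0.0, 0.0, 0.0),
                                time_s=time_s, phase=phase))
        fields.append(t_true)
        for pos, off in zip(sensors, cfg.sensor_offsets_mm):
            trace_rows.append({
                "time_s": time_s,
                "sensor_id": f"sensor_{off:g}mm",
                "temperature_c": float(temperature_at(cfg, pos, time_s)),
            })

    cum_max = np.maximum.reduce(fields)
    truth = GroundTruth(
        temperature_fields=fields,
        necrosis_mask=cum_max >= NECROSIS_TEMP_C,
        applied_shifts=shifts,
        sensor_positions=sensors,
    )
    series = ScanSeries(ablation_id=cfg.ablation_id, scans=scans,
                        probe_tip=tuple(cfg.tip), probe_axis=tuple(cfg.axis))
    trace = TemperatureTrace(
        ablation_id=cfg.ablation_id,
        samples=pd.DataFrame(trace_rows).sort_values(
            ["sensor_id", "time_s"]).reset_index(drop=True),
    )
    return series, trace, truth


def synthesize_calibration_pairs(
    rng: np.random.Generator,
    n_ablations: int = 3,
    n_timepoints: int = 10,
    t_start_c: float = 37.0,
    t_end_c: float = 90.0,
    slope: float = -1.96,
    baseline_hu: float = 55.0,
    core_temp_c: float = 37.0,
    noise_sd_hu: float = 8.0,
) -> pd.DataFrame:
    """Pooled (mean HU, temperature) calibration pairs with pair-level noise.

    Models the upslope measurement directly: each ablation contributes
    ``n_timepoints`` temperatures rising from body temperature to near 90 °C,
    and ROI-mean attenuation follows the linear model plus Gaussian noise on
    the pair level.  Used for slope-recovery and CI-coverage checks without
    the cost of volumetric simulation.
    """
    rows = []
    temps = np.linspace(t_start_c, t_end_c, n_timepoints)
    for a in range(n_ablations):
        hu = baseline_hu + slope * (temps - core_temp_c) + rng.normal(0, noise_sd_hu, n_timepoints)
        for k, (t, h) in enumerate(zip(temps, hu)):
            rows.append({"mean_hu": float(h), "temperature_c": float(t),
                         "ablation_id": f"ablation-{a + 1}", "time_s": 30.0 * k})
    return pd.DataFrame(rows)


def export_case(cfg: PhantomConfig, out_dir: str | os.PathLike) -> dict:
    """Write one synthetic case to disk and return the manifest dict.

    Produces per-scan NIfTI volumes, the sensor-trace CSV, the ground-truth
    necrosis mask, and a YAML manifest consumable by the pipeline CLI.
    Volumes are written uncompressed so re-export with the same seed is
    byte-identical.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    series, trace, truth = synthesize_series(cfg)
    scan_entries = []
    for k, scan in enumerate(series.scans):
        name = f"scan_{k:02d}.nii"
        write_volume(scan, os.path.join(out_dir, name))
        scan_entries.append({"path": name, "time_s": scan.time_s, "phase": scan.phase})
    trace_name = "trace.csv"
    write_temperature_trace(trace, os.path.join(out_dir, trace_name))
    mask_name = "necrosis_mask.nii"
    write_volume(
        VolumeScan(grid=truth.necrosis_mask.astype(np.float64), spacing=cfg.spacing,
                   time_s=cfg.t_end_s, phase="downslope"),
        os.path.join(out_dir, mask_name),
    )
    r70 = analytic_isotherm_radius(cfg)
    manifest = {
        "ablation_id": cfg.ablation_id,
        "probe_tip_mm": [float(x) for x in cfg.tip],
        "probe_axis": [float(x) for x in cfg.axis],
        "macro_diameter_mm": round(float(2.0 * r70), 3),
        "scans": scan_entries,
        "trace": trace_name,
        "necrosis_mask": mask_name,
        "spacing_mm": list(cfg.spacing),
        "seed": cfg.seed,
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def load_case(manifest_path: str | os.PathLike) -> tuple[ScanSeries, TemperatureTrace, dict]:
    """Load an exported case back from its YAML manifest."""
    from .io_volumes import read_temperature_trace, read_volume

    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = os.path.dirname(str(manifest_path))
    scans = [
        read_volume(os.path.join(base, e["path"]), time_s=e["time_s"], phase=e["phase"])
        for e in manifest["scans"]
    ]
    series = ScanSeries(ablation_id=manifest["ablation_id"], scans=scans,
                        probe_tip=tuple(manifest["probe_tip_mm"]),
                        probe_axis=tuple(manifest["probe_axis"]))
    trace = read_temperature_trace(os.path.join(base, manifest["trace"]),
                                   ablation_id=manifest["ablation_id"])
    return series, trace, manifest
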