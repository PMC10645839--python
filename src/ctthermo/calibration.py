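"""HU–temperature calibration from upslope ROI means and invasive sensors.

A circular ROI sized from the macroscopic lesion diameter (plus a small
extension, default 2 mm) is placed perpendicular to the probe at the tip.
For every heating-phase scan the ROI-mean attenuation is paired with the
nearest-in-time invasive temperature; pooled pairs from all ablations feed
Spearman's rank correlation (with a Fisher-z confidence interval) and an
ordinary least-squares fit HU = intercept + slope * T, whose negative slope
(HU/°C) is the calibration constant used to build thermography maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, MatchingError, ParameterError
from .io_volumes import ScanSeries, TemperatureTrace, VolumeScan

DEFAULT_EXTENSION_MM = 2.0
DEFAULT_EXCLUDE_ABOVE_HU = 1000.0  # metal probe
DEFAULT_EXCLUDE_BELOW_HU = -200.0  # gas
UPSLOPE_PHASES = ("pre", "upslope", "peak")


@dataclass(frozen=True)
class CircularROI:
    """Disk ROI in the para-axial plane (normal = probe axis)."""

    center: tuple[float, float, float]
    diameter_mm: float
    plane_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ParameterError("ROI diameter must be positive")

    @classmethod
    def from_macro_diameter(
        cls,
        macro_diameter_mm: float,
        center: tuple[float, float, float],
        plane_normal: tuple[float, float, float] = (0.0, 0.0, 1.0),
        extension_mm: float = DEFAULT_EXTENSION_MM,
    ) -> "CircularROI":
        """ROI exceeding the macroscopic diameter by ``extension_mm``."""
        return cls(center=center, diameter_mm=macro_diameter_mm + extension_mm,
                   plane_normal=plane_normal)


@dataclass
class ROIMean:
    mean_hu: float
    n_included: int
    n_excluded: int


@dataclass
class CalibrationFit:
    """Pooled calibration result: Spearman statistics and the OLS line."""

    pairs: pd.DataFrame
    spearman_r: float
    spearman_ci: tuple[float, float]
    spearman_p: float
    slope_hu_per_c: float
    slope_ci: tuple[float, float]
    intercept_hu: float
    r_squared: float
    n: int
    shapiro_p_hu: float = float("nan")
    shapiro_p_temperature: float = float("nan")

    def summary(self) -> dict:
        return {
            "n": self.n,
            "spearman_r": self.spearman_r,
            "spearman_ci": list(self.spearman_ci),
            "spearman_p": self.spearman_p,
            "slope_hu_per_c": self.slope_hu_per_c,
            "slope_ci": list(self.slope_ci),
            "intercept_hu": self.intercept_hu,
            "r_squared": self.r_squared,
            "shapiro_p_hu": self.shapiro_p_hu,
            "shapiro_p_temperature": self.shapiro_p_temperature,
        }


def roi_mean_hu(
    scan: VolumeScan,
    roi: CircularROI,
    slab_mm: float | None = None,
    exclude_above_hu: float = DEFAULT_EXCLUDE_ABOVE_HU,
    exclude_below_hu: float = DEFAULT_EXCLUDE_BELOW_HU,
) -> ROIMean:
    """Mean attenuation over a disk-of-revolution ROI.

    Voxel centres within radius ``diameter_mm/2`` of the ROI axis and within
    ``slab_mm/2`` of the ROI plane are averaged; voxels outside
    ``(exclude_below_hu, exclude_above_hu)`` — the metal probe, gas, or
    out-of-field sentinels — are excluded and counted.  ``slab_mm`` defaults
    to three voxel layers along the normal.
    """
    normal = np.asarray(roi.plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    spacing = np.asarray(scan.spacing)
    if slab_mm is None:
        slab_mm = 3.0 * float(np.abs(normal) @ spacing)
    if slab_mm < float(np.abs(normal) @ spacing) - 1e-9:
        raise ParameterError("slab_mm must be at least one voxel along the normal")
    xs, ys, zs = scan.voxel_centers()
    rel = np.stack([xs, ys, zs], axis=-1) - np.asarray(roi.center, dtype=float)
    axial = rel @ normal
    radial = np.linalg.norm(rel - axial[..., None] * normal, axis=-1)
    geom = (radial <= roi.diameter_mm / 2.0) & (np.abs(axial) <= slab_mm / 2.0)
    if not geom.any():
        raise DegenerateInputError("ROI does not intersect the volume grid")
    values = scan.grid[geom]
    keep = (values > exclude_below_hu) & (values < exclude_above_hu)
    if not keep.any():
        raise DegenerateInputError("all ROI voxels excluded by the HU thresholds")
    return ROIMean(mean_hu=float(values[keep].mean()),
                   n_included=int(keep.sum()), n_excluded=int((~keep).sum()))


def _select_temperature(trace: TemperatureTrace, time_s: float,
                        max_dt_s: float) -> float | None:
    """Hotter-sensor reading nearest in time, or None if no sample is close."""
    best: float | None = None
    for sensor in trace.sensor_ids:
        grp = trace.sensor(sensor)
        dt = np.abs(grp["time_s"].to_numpy(dtype=float) - time_s)
        k = int(np.argmin(dt))
        if dt[k] <= max_dt_s:
            t = float(grp["temperature_c"].iloc[k])
            if best is None or t > best:
                best = t
    return best


def pair_hu_temperature(
    series: ScanSeries,
    trace: TemperatureTrace,
    roi: CircularROI,
    max_dt_s: float = 15.0,
    slab_mm: float | None = None,
    exclude_above_hu: float = DEFAULT_EXCLUDE_ABOVE_HU,
    exclude_below_hu: float = DEFAULT_EXCLUDE_BELOW_HU,
) -> pd.DataFrame:
    """Pair upslope ROI means with invasive temperatures.

    Heating-phase scans (baseline through peak) are matched to the hotter of
    the two sensors at the nearest sample time; a scan with no sample within
    ``max_dt_s`` raises :class:`MatchingError` naming it.  Pairs carry the
    ablation id so several ablations can be pooled.
    """
    rows = []
    unmatched = []
    for scan in series.scans:
        if scan.phase not in UPSLOPE_PHASES:
            continue
        temp = _select_temperature(trace, scan.time_s, max_dt_s)
        if temp is None:
            unmatched.append(scan.time_s)
            continue
        stats_ = roi_mean_hu(scan, roi, slab_mm=slab_mm,
                             exclude_above_hu=exclude_above_hu,
                             exclude_below_hu=exclude_below_hu)
        rows.append({"mean_hu": stats_.mean_hu, "temperature_c": temp,
                     "ablation_id": series.ablation_id, "time_s": scan.time_s,
                     "n_voxels": stats_.n_included, "n_excluded": stats_.n_excluded})
    if unmatched:
        raise MatchingError(
            f"no temperature sample within {max_dt_s} s of scans at t={unmatched}")
    return pd.DataFrame(rows)


def fit_calibration(pairs: pd.DataFrame | list[tuple]) -> CalibrationFit:
    """Spearman correlation and OLS line on pooled (HU, T) pairs.

    Spearman rho gets a 95% CI by the Fisher z-transform with
    SE = 1.03 / sqrt(n - 3); the OLS slope CI is slope ± t(0.975, n-2) * SE.
    Shapiro–Wilk normality p-values are reported for information only and
    never gate the analysis.
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(pairs, columns=["mean_hu", "temperature_c"])
    n = len(pairs)
    if n < 3:
        raise DegenerateInputError(f"need at least 3 pairs, got {n}")
    hu = pairs["mean_hu"].to_numpy(dtype=float)
    temp = pairs["temperature_c"].to_numpy(dtype=float)
    if np.ptp(temp) == 0:
        raise DegenerateInputError("temperatures have zero variance")

    rho, p = stats.spearmanr(temp, hu)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12 or n <= 3:
        ci = (rho, rho)
    else:
        z = np.arctanh(rho)
        se = 1.03 / np.sqrt(n - 3)
        zc = stats.norm.ppf(0.975)
        ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))

    ols = stats.linregress(temp, hu)
    tcrit = stats.t.ppf(0.975, n - 2)
    slope_ci = (float(ols.slope - tcrit * ols.stderr), float(ols.slope + tcrit * ols.stderr))

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0 or len(x) < 3:
            return float("nan")
        return float(stats.shapiro(x).pvalue)

    return CalibrationFit(
        pairs=pairs.reset_index(drop=True),
        spearman_r=rho,
        spearman_ci=ci,
        spearman_p=float(p),
        slope_hu_per_c=float(ols.slope),
        slope_ci=slope_ci,
        intercept_hu=float(ols.intercept),
        r_squared=float(ols.rvalue ** 2),
        n=n,
        shapiro_p_hu=_shapiro(hu),
        shapiro_p_temperature=_shapiro(temp),
    )
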