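"""Subtraction-CT radial border detection.

The attenuation difference T0 − Tmax (positive in heated tissue) is sampled
along rays fanning out from the probe tip in the para-axial plane — eight
directions by default, each emulating a line of sequential small ROIs.  The
ablation-zone border on a ray is where ΔHU "approaches zero": the first
sampled distance at which the (smoothed) profile falls below a small
threshold and stays below it.  Samples closer than 8 mm to the tip are
excluded, because probe metal and gas generation make central ΔHU
artificially high.  The mean border radius over rays gives a predicted
circular zone area π·r².

Note the subtraction order is the opposite of the thermography module's
(peak − pre there); heated tissue is positive here, so profiles decay
toward zero with distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DetectionError, ParameterError, RegistrationError
from .io_volumes import VolumeScan
from .phantom import _perpendicular

DEFAULT_N_RAYS = 8
DEFAULT_MIN_DISTANCE_MM = 8.0
DEFAULT_EPSILON_HU = 10.0
DEFAULT_SMOOTH_WINDOW = 3


@dataclass
class RadialProfile:
    """ΔHU-vs-distance samples along rays from the probe, plus borders."""

    ray_angles: np.ndarray
    distances_mm: np.ndarray
    delta_hu: np.ndarray = field(repr=False)  # (n_rays, n_distances), NaN off-grid
    min_distance_mm: float
    valid_rays: np.ndarray = field(default=None)  # type: ignore[assignment]
    border_radius_mm: np.ndarray | None = None  # NaN where undetected
    mean_radius_mm: float = float("nan")
    predicted_area_mm2: float = float("nan")

    def __post_init__(self) -> None:
        if self.valid_rays is None:
            self.valid_rays = np.ones(len(self.ray_angles), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, angle in enumerate(self.ray_angles):
            for d, v in zip(self.distances_mm, self.delta_hu[i]):
                rows.append({"ray": i, "angle_rad": float(angle),
                             "distance_mm": float(d), "delta_hu": float(v)})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        borders = (self.border_radius_mm if self.border_radius_mm is not None
                   else np.full(len(self.ray_angles), np.nan))
        return {
            "n_rays": int(len(self.ray_angles)),
            "n_rays_detected": int(np.isfinite(borders).sum()),
            "border_radius_mm": [None if not np.isfinite(b) else float(b) for b in borders],
            "mean_radius_mm": self.mean_radius_mm,
            "predicted_area_mm2": self.predicted_area_mm2,
            "min_distance_mm": self.min_distance_mm,
        }


def _disk_offsets(radius_mm: float, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Fixed in-plane quadrature offsets covering a small disk ROI."""
    if radius_mm <= 0:
        return np.zeros((1, 3))
    step = radius_mm / 2.0
    grid = np.arange(-radius_mm, radius_mm + step / 2, step)
    pts = [(a, b) for a in grid for b in grid if a * a + b * b <= radius_mm ** 2 + 1e-12]
    return np.array([a * u + b * v for a, b in pts])


def radial_profile(
    pre: VolumeScan,
    peak: VolumeScan,
    probe_tip: tuple[float, float, float],
    probe_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    n_rays: int = DEFAULT_N_RAYS,
    step_mm: float = 1.0,
    max_radius_mm: float = 30.0,
    min_distance_mm: float = DEFAULT_MIN_DISTANCE_MM,
) -> RadialProfile:
    """Sample ΔHU = pre − peak along para-axial rays from the probe tip.

    Each sample is the mean over a small disk (radius ``step_mm / 2``) of
    trilinearly interpolated ΔHU, emulating a line of sequential circular
    ROIs.  A ray whose first sample already leaves the grid is marked
    invalid; samples beyond the field of view are NaN.
    """
    if n_rays < 1:
        raise ParameterError("n_rays must be >= 1")
    if not (0 < step_mm <= max_radius_mm):
        raise ParameterError("need 0 < step_mm <= max_radius_mm")
    if (pre.grid.shape != peak.grid.shape or pre.spacing != peak.spacing
            or pre.origin != peak.origin):
        raise RegistrationError("pre and peak scans must share a registered grid")

    delta = pre.grid - peak.grid
    axis = np.asarray(probe_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    u = _perpendicular(axis)
    v = np.cross(axis, u)
    tip = np.asarray(probe_tip, dtype=float)

    angles = np.arange(n_rays) * 2.0 * np.pi / n_rays
    distances = np.arange(min_distance_mm, max_radius_mm + step_mm / 2, step_mm)
    offsets = _disk_offsets(step_mm / 2.0, u, v)

    spacing = np.asarray(pre.spacing)
    origin = np.asarray(pre.origin)
    shape = np.asarray(pre.grid.shape)
    profile = np.full((n_rays, len(distances)), np.nan)
    valid = np.ones(n_rays, dtype=bool)
    for i, ang in enumerate(angles):
        direction = np.cos(ang) * u + np.sin(ang) * v
        centers = tip[None, :] + distances[:, None] * direction[None, :]
        pts = centers[:, None, :] + offsets[None, :, :]  # (n_dist, n_off, 3)
        idx = (pts - origin) / spacing
        inside = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
        vals = ndimage.map_coordinates(delta, idx.reshape(-1, 3).T, order=1,
                                       mode="constant", cval=np.nan).reshape(inside.shape)
        vals[~inside] = np.nan
        sample_ok = np.all(np.isfinite(vals), axis=1)
        profile[i, sample_ok] = vals[sample_ok].mean(axis=1)
        if not sample_ok[0]:
            valid[i] = False
    return RadialProfile(ray_angles=angles, distances_mm=distances, delta_hu=profile,
                         min_distance_mm=min_distance_mm, valid_rays=valid)


def detect_border(
    profile: RadialProfile,
    epsilon_hu: float = DEFAULT_EPSILON_HU,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> RadialProfile:
    """Detect the zone border on each ray and fill the radius fields.

    After centred moving-average smoothing, the border is the smallest
    sampled distance at which ΔHU falls below ``epsilon_hu`` and stays below
    for every larger sampled distance — a sustained approach to zero, robust
    to single noise dips.  Rays that never fall below within the sampled
    range are excluded from the mean; if no ray yields a border a
    :class:`DetectionError` is raised.
    """
    if epsilon_hu <= 0:
        raise ParameterError("epsilon_hu must be positive")
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")
    n_rays, n_d = profile.delta_hu.shape
    borders = np.full(n_rays, np.nan)
    for i in range(n_rays):
        if not profile.valid_rays[i]:
            continue
        y = profile.delta_hu[i]
        finite = np.isfinite(y)
        if not finite.any():
            continue
        last = np.max(np.nonzero(finite))
        y = y[: last + 1]
        if smooth_window > 1:
            y = (pd.Series(y).rolling(smooth_window, center=True, min_periods=1)
                 .mean().to_numpy())
        above = y >= epsilon_hu
        if not above.any():
            borders[i] = profile.distances_mm[0]
            continue
        last_above = int(np.max(np.nonzero(above)))
        if last_above + 1 <= len(y) - 1:
            borders[i] = profile.distances_mm[last_above + 1]
        # else: never settles below epsilon within range -> undetected
    detected = np.isfinite(borders)
    if not detected.any():
        raise DetectionError("no ray shows a sustained fall below epsilon_hu")
    mean_r = float(np.mean(borders[detected]))
    return replace(profile, border_radius_mm=borders, mean_radius_mm=mean_r,
                   predicted_area_mm2=float(np.pi * mean_r ** 2))
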