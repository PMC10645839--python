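"""ΔT mapping and necrosis-zone segmentation from a registered scan pair.

The attenuation difference between the peak-temperature scan and the
baseline scan is converted to a temperature-change map with the calibrated
(negative) HU/°C slope.  Voxels whose ΔT reaches the display threshold —
33 K by default, so that core 37 °C + ΔT exceeds the 70 °C necrosis point —
form the predicted necrosis zone.  The zone is reported as the largest
cross-sectional area in the para-axial plane (perpendicular to the probe),
matching how ablation extent is measured against macroscopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ParameterError, RegistrationError
from .io_volumes import VolumeScan

DEFAULT_THRESHOLD_K = 33.0
DEFAULT_CORE_TEMP_C = 37.0
NECROSIS_TEMP_C = 70.0
DEFAULT_CLAMP_HU = (-300.0, 300.0)
DEFAULT_SMOOTHING_FWHM_MM = 2.0
DEFAULT_EXCLUSION_RADIUS_MM = 8.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def display_threshold_k(necrosis_temp_c: float = NECROSIS_TEMP_C,
                        core_temp_c: float = DEFAULT_CORE_TEMP_C) -> float:
    """ΔT display threshold implied by the necrosis criterion.

    Tissue at core temperature needs a rise of ``necrosis - core`` to reach
    the necrosis point; with the 70 °C criterion and a 37 °C core this is the
    33 K map sensitivity.
    """
    if necrosis_temp_c <= core_temp_c:
        raise ParameterError("necrosis temperature must exceed the core temperature")
    return necrosis_temp_c - core_temp_c


@dataclass
class ThermoMap:
    """Voxelwise ΔT field with the predicted-necrosis mask and its area."""

    delta_hu: np.ndarray = field(repr=False)
    delta_t: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    unreliable: np.ndarray = field(repr=False)
    slope_used: float
    threshold_k: float
    core_temp_c: float
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    area_mm2: float = 0.0
    area_plane_index: int = 0
    area_axis: int = 2
    n_artifact_voxels: int = 0

    def summary(self) -> dict:
        return {
            "slope_hu_per_c": self.slope_used,
            "threshold_k": self.threshold_k,
            "core_temp_c": self.core_temp_c,
            "area_mm2": self.area_mm2,
            "area_plane_index": self.area_plane_index,
            "n_mask_voxels": int(self.mask.sum()),
            "n_artifact_voxels": self.n_artifact_voxels,
        }


def _dominant_axis(probe_axis) -> int:
    return int(np.argmax(np.abs(np.asarray(probe_axis, dtype=float))))


def _distance_from_tip(shape, spacing, origin, probe_tip) -> np.ndarray:
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    grids = np.meshgrid(*axes, indexing="ij")
    rel = np.stack(grids, axis=-1) - np.asarray(probe_tip, dtype=float)
    return np.linalg.norm(rel, axis=-1)


def compute_map(
    pre: VolumeScan,
    peak: VolumeScan,
    slope: float,
    probe_tip: tuple[float, float, float],
    threshold_k: float = DEFAULT_THRESHOLD_K,
    smoothing_fwhm_mm: float = DEFAULT_SMOOTHING_FWHM_MM,
    clamp_hu: tuple[float, float] = DEFAULT_CLAMP_HU,
    exclusion_radius_mm: float = DEFAULT_EXCLUSION_RADIUS_MM,
    core_temp_c: float = DEFAULT_CORE_TEMP_C,
    probe_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> ThermoMap:
    """Build the ΔT map and necrosis mask from a registered (T0, Tmax) pair.

    ΔHU = peak − pre (heated tissue negative) is clamped to ``clamp_hu``,
    optionally Gaussian-smoothed (``smoothing_fwhm_mm``; 0 disables), and
    divided by the negative ``slope`` so heated voxels get positive ΔT.  The
    mask is ΔT ≥ ``threshold_k`` (inclusive); voxels within
    ``exclusion_radius_mm`` of the probe tip, where probe metal and gas
    corrupt ΔHU, join the mask when connected to qualifying neighbours and
    are flagged ``unreliable``.  Finally only the connected component at (or
    nearest to) the probe tip is kept; discarded voxels are counted as
    peripheral artifacts.
    """
    if slope >= 0:
        raise ParameterError("slope must be negative (HU falls with heating)")
    if threshold_k <= 0:
        raise ParameterError("threshold_k must be positive")
    if (pre.grid.shape != peak.grid.shape or pre.spacing != peak.spacing
            or pre.origin != peak.origin):
        raise RegistrationError("pre and peak scans must share a registered grid")

    delta_hu = np.clip(peak.grid - pre.grid, clamp_hu[0], clamp_hu[1])
    if smoothing_fwhm_mm > 0:
        sigma_vox = smoothing_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(pre.spacing)
        delta_hu = ndimage.gaussian_filter(delta_hu, sigma=sigma_vox)
    delta_t = delta_hu / slope

    raw = delta_t >= threshold_k
    unreliable = np.zeros_like(raw)
    mask = raw
    if exclusion_radius_mm > 0:
        dist = _distance_from_tip(pre.grid.shape, pre.spacing, pre.origin, probe_tip)
        near_probe = dist <= exclusion_radius_mm
        # grow the thresholded mask into the corrupted near-probe zone:
        # a near-probe voxel joins if (transitively) adjacent to qualifying tissue
        mask = ndimage.binary_propagation(raw, mask=raw | near_probe)
        unreliable = near_probe & mask & ~raw

    n_before = int(mask.sum())
    mask = _keep_tip_component(mask, pre, probe_tip)
    n_artifact = n_before - int(mask.sum())

    tmap = ThermoMap(delta_hu=delta_hu, delta_t=delta_t, mask=mask,
                     unreliable=unreliable & mask, slope_used=float(slope),
                     threshold_k=float(threshold_k), core_temp_c=float(core_temp_c),
                     spacing=pre.spacing, origin=pre.origin,
                     n_artifact_voxels=n_artifact)
    area, plane = measure_area(tmap, probe_tip, probe_axis)
    tmap.area_mm2 = area
    tmap.area_plane_index = plane
    tmap.area_axis = _dominant_axis(probe_axis)
    return tmap


def _keep_tip_component(mask: np.ndarray, ref: VolumeScan,
                        probe_tip: tuple[float, float, float]) -> np.ndarray:
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    tip_idx = np.clip(np.round(ref.world_to_index(probe_tip)).astype(int),
                      0, np.asarray(mask.shape) - 1)
    lab = labels[tuple(tip_idx)]
    if lab == 0:
        # tip voxel excluded (probe metal): fall back to the nearest component
        coords = np.argwhere(mask)
        d = np.linalg.norm((coords - tip_idx) * np.asarray(ref.spacing), axis=1)
        lab = labels[tuple(coords[int(np.argmin(d))])]
    return labels == lab


def measure_area(
    tmap: ThermoMap,
    probe_tip: tuple[float, float, float],
    probe_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> tuple[float, int]:
    """Largest para-axial cross-section of the mask.

    Planes are taken along the grid axis most aligned with the probe; the
    area of a plane is its mask-voxel count times the in-plane voxel area.
    Returns (area in mm², plane index); an empty mask yields area 0 at the
    plane through the probe tip.
    """
    axis = _dominant_axis(probe_axis)
    in_plane = [a for a in range(3) if a != axis]
    voxel_area = tmap.spacing[in_plane[0]] * tmap.spacing[in_plane[1]]
    if not tmap.mask.any():
        tip_plane = int(round((probe_tip[axis] - tmap.origin[axis]) / tmap.spacing[axis]))
        return 0.0, int(np.clip(tip_plane, 0, tmap.mask.shape[axis] - 1))
    counts = tmap.mask.sum(axis=tuple(in_plane))
    plane = int(np.argmax(counts))
    return float(counts[plane] * voxel_area), plane


def slope_sensitivity_sweep(
    pre: VolumeScan,
    peak: VolumeScan,
    slopes: list[float],
    probe_tip: tuple[float, float, float],
    probe_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    **map_kwargs,
) -> pd.DataFrame:
    """Recompute the map at several slopes (e.g. −0.5 … −1.96).

    With fixed ΔHU, a smaller |slope| maps the same attenuation change to a
    larger ΔT, so the zone grows and peripheral noise voxels increasingly
    cross the threshold; the table reports the measured area and the
    artifact-voxel count (mask voxels pruned outside the main component) for
    each slope.
    """
    rows = []
    for slope in slopes:
        tmap = compute_map(pre, peak, slope, probe_tip, probe_axis=probe_axis,
                           **map_kwargs)
        rows.append({"slope_hu_per_c": slope, "area_mm2": tmap.area_mm2,
                     "artifact_voxels": tmap.n_artifact_voxels,
                     "n_mask_voxels": int(tmap.mask.sum())})
    return pd.DataFrame(rows)


def render_overlay(
    tmap: ThermoMap,
    base: VolumeScan,
    plane_index: int | None = None,
    out_path: str | None = None,
    window_hu: tuple[float, float] = (-100.0, 200.0),
    alpha: float = 0.5,
) -> np.ndarray:
    """Red necrosis-zone overlay on a windowed grayscale CT slice.

    One pixel per voxel (no resampling), so the red pixel count equals the
    in-plane mask count.  Returns the RGB array; writes a PNG if ``out_path``
    is given.
    """
    axis = tmap.area_axis
    if plane_index is None:
        plane_index = tmap.area_plane_index
    if not (0 <= plane_index < base.grid.shape[axis]):
        raise ParameterError(f"plane_index {plane_index} out of range on axis {axis}")
    sl = [slice(None)] * 3
    sl[axis] = plane_index
    hu = base.grid[tuple(sl)]
    mask = tmap.mask[tuple(sl)]
    lo, hi = window_hu
    gray = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    rgb[mask] = (1 - alpha) * rgb[mask] + alpha * np.array([1.0, 0.0, 0.0])
    img = (np.round(rgb * 255)).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(img).save(out_path, format="PNG")
    return img
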