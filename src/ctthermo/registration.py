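"""Rigid alignment of serial scans to the peak-temperature reference.

Each scan is aligned to the scan acquired at maximum temperature, anchored on
a patch around the probe tip, mirroring the clinical choice of the probe tip
as the registration reference point.  Only a rigid translation is estimated:
the series is acquired without table movement, so residual motion is small
and translational.  The translation maximises normalised cross-correlation
over integer-voxel offsets inside a cube around the tip and is refined to
subvoxel precision by a separable quadratic fit of the correlation peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError, RegistrationError
from .io_volumes import SENTINEL_HU, ScanSeries, VolumeScan


@dataclass
class RigidTransform:
    """Moving-to-reference rigid map ``p_ref = R @ p_mov + t`` (mm)."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) > 1e-9:
            raise ParameterError("rotation must be orthonormal")

    @property
    def is_identity_rotation(self) -> bool:
        return bool(np.allclose(self.rotation, np.eye(3), atol=1e-12))

    def apply_point(self, point: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(point, dtype=float) + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(translation=-rt @ self.translation, rotation=rt)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def estimate_rigid(
    moving: VolumeScan,
    reference: VolumeScan,
    probe_tip: tuple[float, float, float],
    search_radius_mm: float = 10.0,
) -> RigidTransform:
    """Estimate the translation aligning ``moving`` onto ``reference``.

    Correlation is restricted to a cube of half-width ``search_radius_mm``
    around the probe tip; integer-voxel offsets up to the same radius are
    scanned and the best is refined per axis by a quadratic fit, ties broken
    toward the smaller-norm translation.  Rotation is fixed to identity.
    """
    if moving.grid.shape != reference.grid.shape or moving.spacing != reference.spacing:
        raise RegistrationError("moving and reference must share grid shape and spacing")
    if search_radius_mm < 0:
        raise ParameterError("search_radius_mm must be >= 0")
    spacing = np.asarray(reference.spacing)
    tip_idx = np.round(reference.world_to_index(probe_tip)).astype(int)
    half = np.maximum(np.ceil(search_radius_mm / spacing).astype(int), 1)

    # reference patch, clipped so every searched offset stays in bounds
    lo = np.maximum(tip_idx - half, half)
    hi = np.minimum(tip_idx + half + 1, np.asarray(reference.grid.shape) - half)
    if np.any(lo >= hi):
        raise RegistrationError("search cube does not fit inside the volume")
    ref_patch = reference.grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if ref_patch.std() == 0:
        raise DegenerateInputError("reference patch has zero variance at the probe tip")

    offsets = sorted(
        product(*(range(-h, h + 1) for h in half)),
        key=lambda v: (v[0] ** 2 + v[1] ** 2 + v[2] ** 2, v),
    )
    scores: dict[tuple[int, int, int], float] = {}
    best_v, best_score = (0, 0, 0), -np.inf
    for v in offsets:
        s = np.asarray(lo) - np.asarray(v)
        e = np.asarray(hi) - np.asarray(v)
        patch = moving.grid[s[0]:e[0], s[1]:e[1], s[2]:e[2]]
        score = _ncc(ref_patch, patch)
        scores[v] = score
        if score > best_score + 1e-12:  # strict improvement keeps smallest-norm ties
            best_v, best_score = v, score

    delta = np.zeros(3)
    if best_score < 1.0 - 1e-9:  # an exact match needs no subvoxel refinement
        for axis in range(3):
            vm = list(best_v)
            vp = list(best_v)
            vm[axis] -= 1
            vp[axis] += 1
            cm = scores.get(tuple(vm))
            cp = scores.get(tuple(vp))
            if cm is None or cp is None:
                continue
            denom = cm - 2.0 * best_score + cp
            if denom < -1e-15:
                delta[axis] = np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5)
    translation = (np.asarray(best_v, dtype=float) + delta) * spacing
    return RigidTransform(translation=translation)


def resample(moving: VolumeScan, transform: RigidTransform) -> VolumeScan:
    """Resample ``moving`` onto the reference grid under ``transform``.

    Trilinear interpolation; voxels mapping outside the field of view are
    filled with :data:`~ctthermo.io_volumes.SENTINEL_HU`.  The identity
    transform returns the grid bitwise unchanged.
    """
    if transform.is_identity_rotation and np.all(transform.translation == 0):
        return replace(moving, grid=moving.grid.copy())
    spacing = np.asarray(moving.spacing)
    origin = np.asarray(moving.origin)
    idx = np.meshgrid(*(np.arange(n, dtype=float) for n in moving.grid.shape), indexing="ij")
    world = np.stack(idx, axis=-1) * spacing + origin
    inv = transform.inverse()
    src = world @ inv.rotation.T + inv.translation  # moving-frame sample points
    coords = (src - origin) / spacing
    grid = ndimage.map_coordinates(
        moving.grid, [coords[..., a] for a in range(3)],
        order=1, mode="constant", cval=SENTINEL_HU,
    )
    return replace(moving, grid=grid)


def register_series(
    series: ScanSeries, search_radius_mm: float = 10.0
) -> tuple[ScanSeries, list[RigidTransform], pd.DataFrame]:
    """Align every scan of a series to its peak scan at the probe tip.

    Returns the registered series, the per-scan transforms, and a tidy table
    of estimated translations (mm).
    """
    reference = series.peak
    registered: list[VolumeScan] = []
    transforms: list[RigidTransform] = []
    rows = []
    for scan in series.scans:
        if scan is reference:
            t = RigidTransform()
            registered.append(replace(scan, grid=scan.grid.copy()))
        else:
            t = estimate_rigid(scan, reference, series.probe_tip, search_radius_mm)
            registered.append(resample(scan, t))
        transforms.append(t)
        rows.append({"time_s": scan.time_s, "phase": scan.phase,
                     "tx_mm": t.translation[0], "ty_mm": t.translation[1],
                     "tz_mm": t.translation[2]})
    out = ScanSeries(ablation_id=series.ablation_id, scans=registered,
                     probe_tip=series.probe_tip, probe_axis=series.probe_axis)
    return out, transforms, pd.DataFrame(rows)
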