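"""Pipeline configuration schema and the seeded end-to-end orchestrator.

The configuration mirrors every stage's parameters with defaults matching
the monitoring protocol: 30 s / 60 s scan intervals, +2 mm ROI extension,
33 K map threshold, 37 °C core temperature, 8 mm near-probe exclusion,
8 subtraction-CT rays.  Unknown keys are rejected up front; one root seed
drives all randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import calibration as cal
from . import phantom as ph
from . import report as rp
from . import subtraction_ct as sct
from . import thermography as tg
from .errors import SchemaError
from .io_volumes import write_temperature_trace, write_volume
from .registration import register_series

log = logging.getLogger("ctthermo")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    baseline_hu: float = 55.0
    true_slope: float = -1.96
    core_temp_c: float = 37.0
    peak_delta_t_c: float = 60.0
    sigma_mm_at_peak: float = 10.0
    noise_sd_hu: float = 8.0
    probe_radius_mm: float = 1.0
    probe_hu: float = 3000.0
    gas_enabled: bool = True
    motion_sd_mm: float = 0.0
    n_upslope: int = 10
    upslope_interval_s: float = 30.0
    n_post: int = 10
    post_interval_s: float = 60.0
    ablation_id: str = "phantom-A"

    @field_validator("true_slope")
    @classmethod
    def _slope_negative(cls, v: float) -> float:
        if v >= 0:
            raise ValueError("true_slope must be negative")
        return v


class RegistrationSection(_Section):
    search_radius_mm: float = 10.0


class CalibrationSection(_Section):
    extension_mm: float = 2.0
    slab_mm: Optional[float] = None
    exclude_above_hu: float = 1000.0
    exclude_below_hu: float = -200.0
    max_dt_s: float = 15.0


class MapSection(_Section):
    slope: Optional[float] = None  # None -> use the fitted calibration slope
    threshold_k: float = 33.0
    core_temp_c: float = 37.0
    smoothing_fwhm_mm: float = 2.0
    clamp_hu: tuple[float, float] = (-300.0, 300.0)
    exclusion_radius_mm: float = 8.0

    @field_validator("slope")
    @classmethod
    def _slope_negative(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v >= 0:
            raise ValueError("slope must be negative")
        return v


class SctSection(_Section):
    n_rays: int = 8
    step_mm: float = 1.0
    max_radius_mm: float = 30.0
    min_distance_mm: float = 8.0
    epsilon_hu: float = 10.0
    smooth_window: int = 3


class ReportSection(_Section):
    cect_areas_mm2: Optional[dict[str, float]] = None


class PipelineConfig(_Section):
    """Schema-validated configuration for the full pipeline run."""

    seed: int = 0
    log_level: str = "INFO"
    phantom: PhantomSection = PhantomSection()
    registration: RegistrationSection = RegistrationSection()
    calibration: CalibrationSection = CalibrationSection()
    map: MapSection = MapSection()
    sct: SctSection = SctSection()
    report: ReportSection = ReportSection()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(raw)
        except pydantic.ValidationError as exc:
            raise SchemaError(str(exc)) from exc

    def phantom_config(self) -> ph.PhantomConfig:
        return ph.PhantomConfig(seed=self.seed, **self.phantom.model_dump())


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> dict:
    """Run simulate → register → calibrate → map → sct → report.

    Every stage writes into its own subdirectory of ``out_dir``; the returned
    manifest lists every produced file with a SHA-256 content hash, so two
    runs with the same configuration and seed are verifiably identical.  Any
    stage failure raises with a message naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = str(out_dir)
    produced: list[str] = []

    def _record(path: str) -> str:
        produced.append(path)
        return path

    stage = "simulate"
    try:
        cfg = config.phantom_config()
        sim_dir = os.path.join(out_dir, "simulate")
        manifest = ph.export_case(cfg, sim_dir)
        for entry in manifest["scans"]:
            _record(os.path.join(sim_dir, entry["path"]))
        for key in ("trace", "necrosis_mask"):
            _record(os.path.join(sim_dir, manifest[key]))
        _record(os.path.join(sim_dir, "manifest.yaml"))
        series, trace, truth = ph.synthesize_series(cfg)
        log.info("simulate: %d scans, necrosis diameter %.1f mm",
                 len(series.scans), manifest["macro_diameter_mm"])

        stage = "register"
        reg_dir = os.path.join(out_dir, "register")
        os.makedirs(reg_dir, exist_ok=True)
        registered, transforms, table = register_series(
            series, config.registration.search_radius_mm)
        for k, scan in enumerate(registered.scans):
            write_volume(scan, _record(os.path.join(reg_dir, f"scan_{k:02d}.nii")))
        table.to_csv(_record(os.path.join(reg_dir, "translations.csv")),
                     index=False, float_format="%.6f")
        log.info("register: max |t| = %.2f mm",
                 max(float(np.linalg.norm(t.translation)) for t in transforms))

        stage = "calibrate"
        cal_dir = os.path.join(out_dir, "calibrate")
        os.makedirs(cal_dir, exist_ok=True)
        roi = cal.CircularROI.from_macro_diameter(
            manifest["macro_diameter_mm"], center=registered.probe_tip,
            plane_normal=registered.probe_axis,
            extension_mm=config.calibration.extension_mm)
        pairs = cal.pair_hu_temperature(
            registered, trace, roi, max_dt_s=config.calibration.max_dt_s,
            slab_mm=config.calibration.slab_mm,
            exclude_above_hu=config.calibration.exclude_above_hu,
            exclude_below_hu=config.calibration.exclude_below_hu)
        fit = cal.fit_calibration(pairs)
        pairs.to_csv(_record(os.path.join(cal_dir, "pairs.csv")),
                     index=False, float_format="%.6f")
        _write_json(fit.summary(), _record(os.path.join(cal_dir, "fit.json")))
        log.info("calibrate: slope %.3f HU/degC (n=%d)", fit.slope_hu_per_c, fit.n)

        stage = "map"
        map_dir = os.path.join(out_dir, "map")
        os.makedirs(map_dir, exist_ok=True)
        slope = config.map.slope if config.map.slope is not None else fit.slope_hu_per_c
        tmap = tg.compute_map(
            registered.pre, registered.peak, slope, registered.probe_tip,
            threshold_k=config.map.threshold_k,
            smoothing_fwhm_mm=config.map.smoothing_fwhm_mm,
            clamp_hu=config.map.clamp_hu,
            exclusion_radius_mm=config.map.exclusion_radius_mm,
            core_temp_c=config.map.core_temp_c,
            probe_axis=registered.probe_axis)
        from dataclasses import replace as _dc_replace
        write_volume(_dc_replace(registered.peak, grid=tmap.delta_t),
                     _record(os.path.join(map_dir, "delta_t.nii")))
        write_volume(_dc_replace(registered.peak, grid=tmap.mask.astype(np.float64)),
                     _record(os.path.join(map_dir, "mask.nii")))
        tg.render_overlay(tmap, registered.peak,
                          out_path=_record(os.path.join(map_dir, "overlay.png")))
        _write_json(tmap.summary(), _record(os.path.join(map_dir, "summary.json")))
        log.info("map: area %.1f mm2 at plane %d", tmap.area_mm2, tmap.area_plane_index)

        stage = "sct"
        sct_dir = os.path.join(out_dir, "sct")
        os.makedirs(sct_dir, exist_ok=True)
        profile = sct.radial_profile(
            registered.pre, registered.peak, registered.probe_tip,
            registered.probe_axis, n_rays=config.sct.n_rays,
            step_mm=config.sct.step_mm, max_radius_mm=config.sct.max_radius_mm,
            min_distance_mm=config.sct.min_distance_mm)
        profile = sct.detect_border(profile, epsilon_hu=config.sct.epsilon_hu,
                                    smooth_window=config.sct.smooth_window)
        profile.to_frame().to_csv(_record(os.path.join(sct_dir, "profiles.csv")),
                                  index=False, float_format="%.6f")
        _write_json(profile.summary(), _record(os.path.join(sct_dir, "summary.json")))
        log.info("sct: mean radius %.1f mm", profile.mean_radius_mm)

        stage = "report"
        rep_dir = os.path.join(out_dir, "report")
        os.makedirs(rep_dir, exist_ok=True)
        # macroscopy stand-in for synthetic cases: ground-truth necrosis extent
        macro_map = tg.ThermoMap(
            delta_hu=np.zeros(truth.necrosis_mask.shape),
            delta_t=np.zeros(truth.necrosis_mask.shape),
            mask=truth.necrosis_mask, unreliable=np.zeros_like(truth.necrosis_mask),
            slope_used=slope, threshold_k=config.map.threshold_k,
            core_temp_c=config.map.core_temp_c,
            spacing=cfg.spacing, origin=(0.0, 0.0, 0.0))
        macro_area, _ = tg.measure_area(macro_map, registered.probe_tip,
                                        registered.probe_axis)
        aid = registered.ablation_id
        cect = config.report.cect_areas_mm2
        comparison = rp.compare_areas({aid: macro_area}, {aid: tmap.area_mm2},
                                      cect if cect else None)
        comparison.to_json(_record(os.path.join(rep_dir, "report.json")),
                           calibration=fit.summary())
        comparison.to_markdown(_record(os.path.join(rep_dir, "report.md")),
                               calibration=fit.summary())
    except Exception as exc:
        from .errors import CTTError
        raise CTTError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_out = {
        "seed": config.seed,
        "files": {os.path.relpath(p, out_dir): _sha256(p) for p in produced},
    }
    _write_json(manifest_out, os.path.join(out_dir, "pipeline_manifest.json"))
    return manifest_out
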