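"""Study-style comparison of ablation areas across measurement methods.

Collects per-ablation areas measured by macroscopy, CT thermography, and
(optionally) contrast-enhanced CT into one table with signed differences and
over/underestimation flags, written as JSON and Markdown.  CECT areas enter
only as externally supplied numbers — segmentation of contrast scans is not
part of this package.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError


@dataclass
class AreaComparison:
    """Per-ablation areas by method with recomputed deltas and flags."""

    table: pd.DataFrame = field(repr=False)

    @property
    def per_ablation(self) -> list[dict]:
        return self.table.to_dict(orient="records")

    def to_json(self, path: str | os.PathLike | None = None,
                calibration: dict | None = None) -> str:
        payload = {"per_ablation": self.per_ablation}
        if calibration is not None:
            payload["calibration"] = calibration
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self, path: str | os.PathLike | None = None,
                    calibration: dict | None = None) -> str:
        lines = ["# Ablation-area comparison", "",
                 "| ablation | macro (mm²) | CTT (mm²) | ΔCTT (mm²) | flag "
                 "| CECT (mm²) | ΔCECT (mm²) | flag |",
                 "|---|---|---|---|---|---|---|---|"]
        for row in self.per_ablation:
            def fmt(key):
                v = row.get(key)
                return "—" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.1f}"
            lines.append(
                f"| {row['ablation_id']} | {fmt('macro_area_mm2')} | {fmt('ctt_area_mm2')} "
                f"| {fmt('ctt_delta_mm2')} | {row.get('ctt_flag', '—')} "
                f"| {fmt('cect_area_mm2')} | {fmt('cect_delta_mm2')} "
                f"| {row.get('cect_flag') or '—'} |")
        if calibration is not None:
            lines += ["", "## Calibration",
                      f"- slope: {calibration.get('slope_hu_per_c'):.3f} HU/°C "
                      f"(95% CI {calibration.get('slope_ci')})",
                      f"- Spearman r: {calibration.get('spearman_r'):.3f} "
                      f"(95% CI {calibration.get('spearman_ci')})",
                      f"- n = {calibration.get('n')}"]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "AreaComparison":
        """Reload a report and verify the stored deltas are self-consistent."""
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["per_ablation"]
        macro = [(r["ablation_id"], r["macro_area_mm2"]) for r in rows]
        ctt = [(r["ablation_id"], r["ctt_area_mm2"]) for r in rows]
        cect = None
        if any(r.get("cect_area_mm2") is not None for r in rows):
            cect = [(r["ablation_id"], r["cect_area_mm2"]) for r in rows]
        rebuilt = compare_areas(macro, ctt, cect)
        for stored, fresh in zip(rows, rebuilt.per_ablation):
            for key in ("ctt_delta_mm2", "cect_delta_mm2", "ctt_flag", "cect_flag"):
                sv, fv = stored.get(key), fresh.get(key)
                both_nan = (isinstance(sv, float) and isinstance(fv, float)
                            and np.isnan(sv) and np.isnan(fv))
                if not both_nan and sv != fv and not (sv is None and fv is None):
                    raise ValidationError(f"stored {key}={sv!r} inconsistent with inputs")
        return rebuilt


def _flag(delta: float) -> str:
    if delta > 0:
        return "over"
    if delta < 0:
        return "under"
    return "equal"


def _as_pairs(values) -> list[tuple[str, float]]:
    if isinstance(values, dict):
        return [(str(k), float(v)) for k, v in values.items()]
    return [(str(k), float(v)) for k, v in values]


def compare_areas(macro, ctt, cect=None) -> AreaComparison:
    """Build the per-ablation comparison table.

    ``macro``/``ctt``/``cect`` are dicts or (ablation_id, area_mm2) pairs with
    matching ids; deltas are method − macroscopy, a positive delta flagging
    overestimation of the true (macroscopic) zone.
    """
    macro_p, ctt_p = _as_pairs(macro), _as_pairs(ctt)
    ids = [k for k, _ in macro_p]
    if [k for k, _ in ctt_p] != ids:
        raise ValidationError("macro and CTT ablation ids do not match")
    cect_map: dict[str, float] = {}
    if cect is not None:
        cect_p = _as_pairs(cect)
        if [k for k, _ in cect_p] != ids:
            raise ValidationError("macro and CECT ablation ids do not match")
        cect_map = dict(cect_p)
    for name, pairs in (("macro", macro_p), ("ctt", ctt_p)):
        if any(a < 0 for _, a in pairs):
            raise ValidationError(f"negative {name} area")
    rows = []
    for (aid, m), (_, c) in zip(macro_p, ctt_p):
        row = {"ablation_id": aid, "macro_area_mm2": m, "ctt_area_mm2": c,
               "ctt_delta_mm2": c - m, "ctt_flag": _flag(c - m),
               "cect_area_mm2": None, "cect_delta_mm2": None, "cect_flag": None}
        if aid in cect_map:
            e = cect_map[aid]
            row.update(cect_area_mm2=e, cect_delta_mm2=e - m, cect_flag=_flag(e - m))
        rows.append(row)
    return AreaComparison(table=pd.DataFrame(rows))


def macro_area_from_diameters(d1_mm: float, d2_mm: float,
                              mode: str = "circle-of-mean") -> float:
    """Lesion area from the two measured diameters of a bisected sample.

    ``circle-of-mean`` treats the lesion as a circle with the mean diameter,
    π·((d1+d2)/4)²; ``ellipse`` uses π·d1·d2/4.  Both are conveniences —
    planimetric areas traced from photographs need not match either.
    """
    if d1_mm <= 0 or d2_mm <= 0:
        raise ParameterError("diameters must be positive")
    if mode == "circle-of-mean":
        return float(np.pi * ((d1_mm + d2_mm) / 4.0) ** 2)
    if mode == "ellipse":
        return float(np.pi * d1_mm * d2_mm / 4.0)
    raise ParameterError(f"unknown mode {mode!r}")
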