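# ctthermo — CT-based thermography for thermal-ablation monitoring

Percutaneous microwave and radiofrequency ablation destroy liver tumours by
heating; treatment success hinges on whether the necrosis zone covered the
tumour margin, and no routine imaging can verify that *during* the
procedure. CT-based thermography (CTT) exploits the fact that tissue
attenuation falls approximately linearly as temperature rises,

        HU(T) = HU₀ + a · (T − T_core),    a < 0  (HU/°C),

so the attenuation difference between a pre-ablation scan (T₀) and the scan
at peak temperature (T_max) becomes a voxelwise temperature-change map

        ΔT = (HU_Tmax − HU_T0) / a .

With a core temperature of 37 °C and the 70 °C tissue-necrosis point, voxels
with **ΔT ≥ 33 K** form the predicted necrosis zone, displayed as a red
overlay and measured as the largest cross-section in the para-axial plane
(perpendicular to the probe).

`ctthermo` implements this pipeline for interventional-radiology and
image-analysis researchers:

- **Calibration** — ROI-mean attenuation over the heating phase paired with
  invasive fiberoptic temperatures; pooled Spearman correlation (Fisher-z
  CI) and OLS slope with 95% CI.
- **Registration** — rigid alignment of every serial scan to the
  peak-temperature scan, anchored on a patch at the probe tip (normalised
  cross-correlation, subvoxel quadratic refinement).
- **Thermography** — ΔT map, 33 K necrosis mask with near-probe artifact
  handling, para-axial area, slope-sensitivity sweep, red PNG overlay.
- **Subtraction CT (SCT)** — ΔHU(T₀ − T_max) profiles along 8 rays from the
  probe; the zone border is where ΔHU durably approaches zero; the mean
  radius predicts the zone area π·r².
- **Synthetic phantom** — a heated-liver simulator (Gaussian radial heating,
  linear HU–T coupling, hyperdense probe, gas blobs, noise, rigid motion)
  with closed-form isotherm radii, so every stage can be validated against
  analytic ground truth.

## Worked example

```python
import numpy as np
from ctthermo import (PhantomConfig, synthesize_series, compute_map,
                      analytic_isotherm_radius, radial_profile, detect_border)

cfg = PhantomConfig(shape=(96, 96, 24), noise_sd_hu=0, gas_enabled=False,
                    probe_radius_mm=0, n_upslope=2, n_post=0)
series, trace, truth = synthesize_series(cfg)

tmap = compute_map(series.pre, series.peak, slope=-1.96,
                   probe_tip=tuple(cfg.tip),
                   smoothing_fwhm_mm=0, exclusion_radius_mm=0)
print(f"analytic 70 degC isotherm radius: {analytic_isotherm_radius(cfg):.2f} mm")
print(f"predicted necrosis area:          {tmap.area_mm2:.1f} mm^2")
print(f"equivalent radius:                {np.sqrt(tmap.area_mm2/np.pi):.2f} mm")

prof = detect_border(radial_profile(series.pre, series.peak,
                                    tuple(cfg.tip), tuple(cfg.axis)),
                     epsilon_hu=10.0)
print(f"SCT mean border radius:           {prof.mean_radius_mm:.1f} mm")
```

prints

```
analytic 70 degC isotherm radius: 10.93 mm
predicted necrosis area:          376.0 mm^2
equivalent radius:                10.94 mm
SCT mean border radius:           23.0 mm
```

The thermography mask recovers the closed-form 33 K isotherm radius
(10.93 mm) to a hundredth of a millimetre on this noiseless phantom. The
SCT border with a 10 HU threshold sits farther out (23 mm): it detects where
*any* heating fades into noise, not the 33 K isotherm; setting
`epsilon_hu = |slope| * 33` instead places it on the necrosis boundary
(cross-checked in the test suite).

## Command line

```bash
ctt simulate  --config cfg.yaml --out case/ --seed 1     # synthetic case
ctt register  --manifest case/manifest.yaml --out reg/
ctt calibrate --manifest case/manifest.yaml --out fit.json
ctt map       --pre pre.nii --peak peak.nii --slope -1.96 --tip X Y Z --out map/
ctt sct       --pre pre.nii --peak peak.nii --tip X Y Z --out sct/
ctt report    --areas areas.yaml --out report
ctt run       --config cfg.yaml --seed 1 --out out/      # full pipeline
```

`ctt run` executes simulate → register → calibrate → map → sct → report and
writes a manifest with SHA-256 hashes of every artifact; reruns with the
same seed are byte-identical.

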