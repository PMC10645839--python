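# Methods

## The measurement model

CT-based thermography rests on a single physical regularity: over the
temperature range of thermal ablation, soft-tissue attenuation decreases
approximately linearly with temperature. Writing `a` (HU/°C, negative) for
that sensitivity, a registered pre-ablation scan (T₀) and peak-temperature
scan (T_max) give a voxelwise temperature change

    ΔT(x) = (HU_Tmax(x) − HU_T0(x)) / a .

Tissue necrosis is taken as certain once local temperature has reached
70 °C. At a core (body) temperature of 37 °C this fixes the display rule:
a voxel is in the predicted necrosis zone iff ΔT ≥ 33 K
(`display_threshold_k`). Both constants are parameters (`core_temp_c`,
`threshold_k`); their defaults encode this criterion.

The slope `a` is not assumed — it is calibrated per experiment: ROI-mean
attenuation in heating-phase scans is paired with invasive fiberoptic
temperature readings, pooled across ablations, and fitted by ordinary least
squares (with Spearman's rank correlation reported alongside, since the
pairs are not normally distributed in general).

## Pipeline stages and their key parameters

### Acquisition model (`io_volumes`)

A monitored ablation is a fixed-table serial acquisition: scan 1 is the
baseline at t = 0 (phase `pre`), upslope scans follow every
`upslope_interval_s` (default 30 s) with the last labelled `peak`, then
post-ablation scans every `post_interval_s` (default 60 s). Defaults model
the 10 + 10 protocol (20 scans per ablation). Volumes are exchanged as
axis-aligned scalar NIfTI-1 in mm; a voxel centre sits at
`origin + index * spacing`. Acquisition times are exact interval multiples;
per-scan clock offsets are not modelled, and the thermometer-to-scan
matching window (15 s, half the shortest interval) absorbs any offset.

### Synthetic phantom (`phantom`)

The generator emulates the statistical structure the analysis assumes, not
liver biophysics. Temperature around the probe segment is radial-Gaussian:

    T(x, t) = T_core + A(t) · exp(−d(x)² / 2σ(t)²)

with amplitude `A` ramping linearly from 0 to `peak_delta_t_c` (default
60 °C) over the upslope and halving once per post-ablation interval
afterwards, and width `σ` growing from `σ_peak/2` to `σ_peak` (default
10 mm) over the upslope. This form is chosen *because* its isotherms are
closed-form — `r(T*) = σ·sqrt(2·ln(A/(T*−T_core)))` — so segmentation
accuracy is checkable analytically; it ignores perfusion, vaporisation
enthalpy and tissue anisotropy. Attenuation follows the linear model with
`baseline_hu = 55`, `true_slope = −1.96 HU/°C`; confounds are a hyperdense
probe cylinder (3000 HU, radius 1 mm), seeded hypodense gas blobs
(−700 HU) within 8 mm of the tip on heating scans only, per-voxel Gaussian
noise (default SD 8 HU) and optional per-scan rigid shifts. Two simulated
sensors run parallel to the probe at 5 and 10 mm lateral offset — a
generator default, as real probe-to-sensor distances are not standardised.

Probe and gas are rendered with linear partial-volume blending over about
one voxel. This matters: a hard-thresholded cylinder carries aliased
position information, and registration against it is biased by up to ~0.7
voxel regardless of noise; with partial volume — as on a real scanner — the
probe edge encodes subvoxel position faithfully.

The ground-truth necrosis mask uses the *cumulative maximum* temperature
(≥ 70 °C), so cooling never shrinks it. Determinism: one root seed, split
per scan index and purpose via SHA-256, fixes every random draw; volumes
are exported uncompressed (.nii) so re-export is byte-identical.

What passing phantom tests do **not** show: performance under elastic
(breathing) deformation, perfusion-driven asymmetric heating, beam-
hardening streaks, or contrast-enhanced anatomy. The phantom's motion is
purely rigid, matching the scope of the registration stage.

### Registration (`registration`)

Each scan is aligned to the peak scan — the clinical reference, anchored at
the probe tip — by a rigid translation only. Rotation is not estimated: the
series is acquired without table movement, so residual motion within a
breath-held series is small and translational, and the phantom generates
only rigid shifts. The vendor's elastic pre-step is not reproduced (its
parameters are unpublished); elastic deformation is out of scope.

The translation maximises zero-mean normalised cross-correlation over
integer-voxel offsets within a cube of half-width `search_radius_mm`
(default 10) centred on the tip, then is refined per axis by a quadratic
fit of the correlation peak (refinement skipped when the integer peak is
already exact; ties broken toward the smaller-norm shift; refinement
clipped to ±0.5 voxel). On moving noisy phantoms this recovers shifts to
~0.1 voxel. Resampling is trilinear; out-of-field voxels carry the sentinel
−32768 HU, which every downstream HU filter excludes.

### Calibration (`calibration`)

The ROI is a disk of revolution: diameter = macroscopic lesion diameter
+ 2 mm extension, normal along the probe, slab three voxel layers thick
(defaults). Voxels outside (−200, 1000) HU are excluded — gas, probe metal
and sentinels; whether the original analyses excluded probe metal is
unknown, so the thresholds are explicit parameters. Pairing takes, per
heating-phase scan, the *hotter* of the two sensors at the nearest sample
time (≤ 15 s); which sensor fed the published calibration is unstated, and
the hotter-sensor rule is the deterministic documented choice. Pairs pool
across ablations unweighted.

The fit reports Spearman rho with a Fisher-z 95% CI (SE = 1.03/√(n−3); the
construction behind published CIs is typically unstated, and this is the
textbook choice), the OLS slope with t-based 95% CI, r², and Shapiro–Wilk
normality p-values for information only — they never gate the analysis.

A structural caveat the phantom makes visible: ROI-mean ΔHU averages the
radial heating profile while the sensor reads a point 5 mm out, so the
fitted "effective" slope is attenuated toward zero relative to the
voxel-level sensitivity (≈ −1.65 vs −1.96 on the default phantom). This is
a property of ROI-based calibration itself, not an implementation error;
pair-level recovery (noise added directly on ROI means,
`synthesize_calibration_pairs`) is unbiased and its 95% CI shows nominal
coverage.

### Thermography (`thermography`)

ΔHU = peak − pre is clamped to ±300 HU (bounds gas/probe-driven absurd ΔT;
configurable), optionally Gaussian-smoothed (default FWHM 2 mm; 0
reproduces raw behaviour — the vendor display's internals are unpublished,
so smoothing is explicit and switchable), and divided by the negative
slope. The mask is ΔT ≥ 33 K, *inclusive*. Within `exclusion_radius_mm`
(default 8 mm — the radius inside which probe metal and gas corrupt ΔHU)
non-qualifying voxels join the mask by geodesic propagation from qualifying
neighbours and are flagged unreliable, so the probe core does not punch a
hole through the zone. Finally only the connected component containing the
probe tip survives (nearest component if the tip voxel itself is excluded);
pruned voxels are counted as peripheral artifacts, the quantity that grows
sharply as |slope| shrinks in the sensitivity sweep.

Area is the *largest* single para-axial cross-section (mask count × voxel
area), not a volume — matching how ablation extent is compared with
bisected macroscopic specimens. Planes are taken along the grid axis most
aligned with the probe; for oblique probes the stack should be reformatted
first. Whether published CTT areas were planimetric or mask counts is not
recoverable; mask counting is the reproducible choice.

### Subtraction CT (`subtraction_ct`)

ΔHU here is T₀ − T_max — positive in heated tissue, the opposite sign
convention from the thermography stage; both are documented and their
consistency is tested. Profiles are sampled along 8 para-axial rays at
1 mm steps from 8 mm (inside which central ΔHU is artificially high) to
30 mm, each sample disk-averaged (radius step/2) to emulate sequential
small ROIs. "ΔHU approaching zero" is operationalised as the first sampled
distance at which the moving-average-smoothed profile falls below
`epsilon_hu` (default 10 HU ≈ 1.25× the default noise SD) **and stays
below** at all larger sampled distances — the sustained-crossing rule
resists single noise dips. Rays without a sustained crossing are excluded
from the mean (and counted); the predicted area is π·(mean radius)².
With ε matched to the map threshold (|a|·33 HU) the SCT radius lands on
the thermography mask boundary within one step.

### Report (`report`)

Per-ablation areas by method (macroscopy, CTT, optional externally supplied
CECT) with signed deltas and over/under flags, as JSON and Markdown; deltas
are recomputed on load and verified. `macro_area_from_diameters` exposes
both the circle-of-mean (π·((d₁+d₂)/4)²) and ellipse (π·d₁d₂/4) formulas,
because planimetric areas traced from photographs need not match either.
For synthetic pipeline runs the "macroscopy" stand-in is the ground-truth
necrosis mask's largest cross-section.

### Orchestration (`config`, `cli`)

A pydantic schema (unknown keys rejected, slope-sign checked before any
stage runs) drives simulate → register → calibrate → map → sct → report;
one root seed fixes all randomness, each stage writes only inside its
output directory, and the final manifest hashes every artifact (SHA-256),
making reproducibility checkable at the byte level. By default the map
stage uses the freshly fitted slope; `map.slope` pins it externally.

## Numerical choices and degenerate inputs

- Threshold comparisons are inclusive (ΔT ≥ 33, border `< ε`).
- NCC of a zero-variance reference patch, an all-excluded ROI, fewer than
  3 calibration pairs, zero temperature variance, and a profile that never
  falls below ε all raise typed errors rather than returning numbers.
- Quadratic refinement divides only by a strictly negative curvature;
  degenerate curvature leaves the integer estimate.
- Spearman CI collapses to a point when |rho| = 1 (Fisher z diverges).
- An empty mask reports area 0 at the plane through the probe tip.

## Problem sizes

Tests and the acceptance script run phantoms of 48–96 voxels per axis at
1 mm spacing with 2–6 scans per series where the full 20-scan protocol is
not itself under test; these sizes keep every closed-form check (isotherm
radii up to ~22 mm, registration search up to ±8 mm) fully inside the
volume while the whole suite completes in well under a minute of compute.

## Known limitations

- Rigid, translation-only registration; no elastic model.
- Area measurement assumes a near-axis-aligned probe.
- The phantom's Gaussian heat profile is a validation device, not a bioheat
  model; quantitative claims about real perfused liver require real data.
- CECT areas are inputs, never computed.
- The effective-slope attenuation of ROI-based calibration (above) applies
  equally to any experiment that pairs ROI means with point sensors.
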