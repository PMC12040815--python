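# Methods

This note documents the models behind `cbctbrachy`, the default parameters
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Coordinate and grid conventions

All world coordinates are right-handed, in millimetres, with +z cranial;
needle insertion defaults to +z ("deeper into the pelvis"), which fixes the
sign of the enhanced insertion depth (EID) unambiguously. Voxel grids are
node-centred: the world position of index (i, j, k) is
`origin + index * spacing`; binary masks use voxel-centre membership with no
partial-volume weighting. ROI disk membership likewise uses voxel centres.
These conventions trade sub-voxel precision for exact reproducibility.

## Synthetic phantom

The phantom is a deliberately simple geometric stand-in for a pelvic CBCT:
ellipsoidal fat, uterus (with an HR-CTV sub-ellipsoid), bladder, rectum and
two lateral bone bodies, with sizes proportional to the volume extent so any
volume ≥ 32³ voxels hosts a consistent anatomy. The default volume is 128³
voxels at 1 mm — desk-scale rather than the 0.6 mm of a clinical CBCT
reconstruction; spacing is configurable.

Voxel HU is `class mean + N(0, class_sd²) + N(0, noise_sd²)`: the first term
models textural tissue variability, the second imaging noise, so the
population SD inside a tissue ROI is `sqrt(class_sd² + noise_sd²)`. The
default means (uterus 45, bladder −35, fat −91, background 20, bone 700,
applicator 1200 HU; class SD 5, noise SD 15.2) were chosen once so the
*population* contrast-to-noise ratios are 5.0 between bladder and uterus and
8.5 between uterus and fat — the neighbourhood of values observed clinically
on intraoperative CBCT — while keeping individual HU values plausible.
Bladder HU is lower than urine in a diagnostic CT; it was bent downward to
realize the clinical CNR pair with a common noise level. The applicator mean
must exceed every soft-tissue mean by ≥ 200 HU (validated), so profile peaks
are detectable by construction.

An optional streak artifact (low-frequency sinusoidal HU modulation) exists
as a stress input only; it is a placeholder, not a physical scatter/motion
model, and no quantitative claim depends on it.

The generator does **not** emulate: CBCT projection/reconstruction physics,
scatter or beam hardening, metal artifacts, organ deformation, inter-observer
reconstruction variability, or realistic anatomy. Passing tests therefore
demonstrate the correctness of the *measurement machinery* on known ground
truth, not the clinical values obtainable on real scans.

## Implant model

The intrauterine probe is a planar unit-speed curve whose curvature varies
linearly along arc length (defaults κ₀ = 0.004 mm⁻¹, κ₁ = 5·10⁻⁵ mm⁻²,
length 55 mm, ≈ 19° total bend). A constant-curvature arc is congruent to
itself end-to-end, which would make rigid registration recovery ambiguous;
the linear curvature gradient breaks that symmetry while remaining "a
curvature parameter". Needles are straight, parallel, equally spaced along x,
inserted from the entry plane z = 0; ovoids are short, slightly bowed tracks
at ±standoff. All tracks are ordered tip-first, and the insertion direction
of a track is the tangent of its tip segment.

Paired scenarios: the planning-frame implant is the intraoperative implant
with each needle retracted by its recorded depth shift (the ground-truth
EID), mapped through the true rigid transform, plus optional per-point
Gaussian jitter. With zero jitter the truth is exactly recoverable, which is
what the recovery tests assert.

## Image-quality measures

CNR follows the two-ROI definition above. Line profiles run along the world
x ("lateral") or y ("vertical") axis through the applicator tip's axial
slice, sampled at voxel-spacing steps with trilinear interpolation. The peak
window is ±2 mm around the tip — wide enough to contain the ~1.6–2 mm
applicator diameter class — and the background is every remaining sample not
covered by an exclusion mask (applicator/bone labels from synthetic truth;
for real scans an HU threshold mask can be supplied instead). Zero-variance
delta samples in the peak-visibility t-test use the convention p = 0 if the
mean is positive, else 1.

## Registration and geometry

Tracks are resampled at 0.5 mm arc-length steps from the tip before any
comparison. The ICP variant is point-to-point: nearest-neighbour
correspondences, closed-form SVD rigid fit per iteration, initialization by
centroid alignment plus principal-axes rotation with two rotational starts
(the 180° ambiguity about the principal axis); the start with the lower
final MAE wins, deterministically. Plain ICP guarantees a non-increasing
mean *squared* error; because the package reports mean *absolute* error, the
implementation evaluates the nearest-neighbour MAE after each update and
stops (rejecting the step) if it would increase — the recorded trace is
therefore non-increasing by construction. Convergence is declared when the
MAE improves by less than 10⁻⁶ mm, with a 200-iteration cap. Collinear point
sets are registered but flagged: rotation about the line axis is
unconstrained.

Cross-scan MAE for ovoids and needles corresponds points by arc-length index
from the tip, the shorter curve truncating both. EID signs use the
projection of the tip displacement onto the first-scan tip tangent, with a
zero projection counted as positive (shifted deeper). The cranial HR-CTV
border on masks is the plane tangent to the mask at its maximum z; tips at
or beyond it "reach the border" and report no distance. Ray marching uses
0.05 mm steps with the entry position taken at the midpoint of the
bracketing steps, so measured distances carry a half-voxel offset relative
to an idealized continuous border — documented, not corrected.

## Dose engine and planning

The engine is the TG-43 point-source form: dose = Σ dwells
`time · rate · (10/r)² · g(r) · F(r)`, with g(10 mm) = 1 and g ≡ 1 by
default so every geometric test has a closed form; a consensus g(r) table
can be supplied. The near field is clamped at r = 0.5 mm. The line-source 2D
formalism, heterogeneity corrections and transit dose are out of scope: all
cohort-level results are relative to the prescription, so the absolute
engine scale cancels.

Dwells step at 2.5 mm from applicator-specific tip offsets: 6 mm for the
intrauterine probe, 5/9 mm for plastic/metal needles. The ovoid offset is
not independently specified anywhere authoritative; 6 mm (probe-like thimble
geometry) is used. The virtual needle shift edits the planning-system
reconstruction offset (the negative of the tip offset): retraction r makes a
plastic needle's offset −5 − r. This is exactly equivalent to translating
the needle's dwells r mm caudally along the track, and that equivalence is
asserted to 10⁻⁹ of the maximum dose.

The dwell-time optimizer is a deterministic stand-in for manual forward
planning: non-negative least squares driving HR-CTV surface-sample doses
toward the planning aim, plus a hinge penalty (active-set iteration, weight
10, ≤ 20 passes) on OAR surface samples above their physical limits. The
limits derive from the clinical EQD2 constraints (85 Gy bladder, 75 Gy
rectum, minus a 45 Gy EQD2 external-beam contribution) converted to physical
dose at 0.5 Gy per pulse with α/β = 3 Gy. The retraction study aims the
target surface at 1.2× prescription, which emulates the clinical objective
of full coverage under OAR restraint and lands the optimized plans at
V100 ≈ 98% and D90 ≈ 115–120% of prescription — the clinically observed
regime. No claim is made that this optimizer reproduces any clinical
planner; all assertions about it are property-based (closed forms, symmetry,
comparison against exhaustive search, and directional behaviour).

DVH metrics sort whole voxels with voxel-volume weighting on a 1 mm default
grid: D90 is the largest dose received by ≥ 90% of the structure volume,
V100 the volume fraction at or above prescription, D2ccm the minimum dose in
the hottest 2 cm³ (structures below 2 cm³ report their minimum dose,
flagged). EQD2 uses `D(d + α/β)/(2 + α/β)` with defaults α/β = 10 Gy for
target and 3 Gy for OARs; pulsed-dose-rate incomplete-repair kinetics are
deliberately ignored and the per-pulse dose stands in for the fraction dose
— a stated limitation.

## Cohort generator and statistics

Synthetic cohorts draw per-patient V100/D90/D2ccm from Gaussian baselines
(V100 97.2 ± 2.5%, D90 111 ± 5%, bladder D2ccm 64 ± 14%, rectum 42 ± 14% —
the "previous workflow" regime), with configurable additive effects on the
second arm; the preset effect mirrors the observed cohort-level change. V100
draws are not clipped at 100%: clipping would bias the configured mean, and
only the synthetic sampler (not DVH metrics from actual dose grids) can
exceed 100. With zero effect the arms are exchangeable, which is what the
type-I calibration tests exploit.

Welch's and the paired t-test report two-sided p-values (the one-sided
variant exists only for profile-peak visibility); confidence intervals are
t-based; no multiple-testing correction is applied, matching the reporting
style the package mirrors. Zero-variance difference samples follow the same
convention as above.

## Problem sizes used in the validation suite

The test suite runs phantoms at 48³–128³ voxels, ICP recovery over 100
random rigid transforms (rotations ≤ 20°, translations ≤ 20 mm), 2,000-
replicate null calibrations per test, a 61³/121³-point analytic sphere for
the DVH closed forms, and 20 seeded retraction-study scenarios. These sizes
were chosen as the smallest that make the statistical assertions sharp
(binomial bands of ±1%, Monte-Carlo means within 4 standard errors).

## Known limitations

- The phantom's simplicity means image-quality results validate the metric
  implementations, not CBCT physics.
- The streak-artifact model is qualitative only.
- Ovoid curve correspondence for MAE is by arc-length index — a package
  decision, since no canonical parameterization exists for it.
- The optimizer is a stand-in; absolute dwell times and absolute dose levels
  carry no clinical meaning, only relative/% quantities do.
- Sub-voxel geometry (border distances, ROI membership) carries half-voxel
  conventions documented above.
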