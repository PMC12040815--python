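# cbctbrachy

Quantitative assessment toolkit for intraoperative CBCT-guided gynecologic
brachytherapy. The package is aimed at medical physicists who want to quantify
what intraoperative cone-beam CT adds to an ultrasound-guided implantation
workflow for cervical-cancer brachytherapy: how well tissues and applicator
tips are visible on the scans, how much needle geometry improves, and what
that is worth dosimetrically — all exercised end-to-end on synthetic pelvic
phantoms with known ground truth.

## What it computes

**Image quality.** Circular-ROI statistics and the contrast-to-noise ratio
between two tissues,

    CNR = |#CT_x − #CT_y| / sqrt((σ_x² + σ_y²) / 2),

plus lateral/vertical CT-number line profiles through each applicator tip
(peak vs background excluding adjacent applicators and bone) with a one-sided
one-sample t-test of peak visibility.

**Implant geometry.** Applicator polylines are resampled at 0.5 mm from the
tip; the intrauterine probe of one scan is rigidly registered to the other
with a point-to-point ICP (SVD rigid fit per iteration, nearest-neighbour
correspondences), and implant fidelity is summarized by the mean absolute
error MAE = Σₙ |RP₁,ₙ − RP₂,ₙ| / N over corresponded points. The enhanced
insertion depth (EID) of a needle between two scans is the signed tip
displacement ±|AB| (positive = shifted deeper along the insertion direction),
and needles short of the target are characterized by the ray-marched distance
from tip to the cranial HR-CTV border.

**Dosimetry.** A TG-43-style point-source engine (inverse square × radial dose
function g(r), g(10 mm) = 1, optional anisotropy) drives dwell positions
stepped at 2.5 mm from applicator-specific tip offsets (6 mm probe, 5 mm
plastic needle, 9 mm metal needle), a deterministic non-negative least-squares
dwell-time optimizer with EQD2-derived OAR hinge penalties, DVH metrics
(D90, V100, D2ccm, all in % of prescription), EQD2 = D(d + α/β)/(2 + α/β),
and the D2ccm/D90 tradeoff ratio. The virtual needle-shift simulation
retracts a needle by editing its reconstruction offset exactly as a planning
system would: a plastic needle retracted 10 mm caudally gets an offset of
−15 mm.

**Statistics.** Welch's t-test, the paired t-test, the one-sided one-sample
t-test, t-based 95% confidence intervals, and two-arm cohort comparison
tables (means ± SD, ranges, CIs, p-values).

**Synthetic data.** Everything above runs on generated inputs: pelvic
CBCT-like HU volumes (ellipsoidal uterus/bladder/fat/bone plus Gaussian
noise and optional streak artifacts), implants of a curved intrauterine
probe, ovoids and parallel needles, paired intraop/planning scenarios with a
known rigid transform and known per-needle depth shifts, and two-arm
dosimetric cohorts with configurable effect sizes.

## Worked example

```python
import cbctbrachy as cb

# virtual retraction of a plastic needle by 10 mm -> planning offset
cb.virtual_shift_offset("plastic_needle", 10.0)   # -15.0

# image quality on a synthetic phantom
from cbctbrachy.synthetic import suggested_rois
truth = cb.ScenarioTruth(seed=3)
vol, masks = cb.generate_phantom_volume(truth)
stats = {r.label: cb.roi_stats(vol, r) for r in suggested_rois(vol)}
cb.cnr(stats["bladder"], stats["uterus"])   # 4.74  (population value 5.0)
cb.cnr(stats["uterus"], stats["fat"])       # 8.40  (population value 8.5)

# dosimetric cost of suboptimal needle depth (14 mm retraction, re-optimized)
res = cb.run_retraction_study(seed=1, retraction_mm=14.0)
res["clinical"]    # {'v100': 98.19, 'd90': 116.74, 'd2ccm_bladder': 68.45,
                   #  'd2ccm_rectum': 64.20, 'ratio_bladder': 0.586, ...}
res["retracted"]   # {'v100': 95.28, 'd90': 112.46, 'd2ccm_bladder': 69.00,
                   #  'd2ccm_rectum': 64.48, 'ratio_bladder': 0.614, ...}
```

The retraction study reads: with needle tips adjusted to the cranial HR-CTV
border the optimized plan covers 98.2% of the target at prescription
(D90 = 117% of prescription); virtually retracting every needle 14 mm
caudally and re-optimizing drops coverage to 95.3% (D90 = 112%) while the
bladder and rectum receive *more* dose per unit target dose
(D2ccm/D90 ratios rise from 0.59/0.55 to 0.61/0.57) — the dosimetric benefit
of intraoperative depth correction.

A CLI mirrors the layers: `cbctbrachy synth phantom|cohort`,
`cbctbrachy iq cnr|profiles`, `cbctbrachy geo register|eid`,
`cbctbrachy dose plan|dvh|vshift`, `cbctbrachy stats compare`.

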