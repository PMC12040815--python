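"""Synthetic pelvic CBCT scenarios with recorded ground truth.

This module generates every input the assessment pipeline consumes: CBCT-like
HU volumes with ellipsoidal uterus / bladder / fat / bone compartments and
rasterized applicators, structure masks (HR-CTV, bladder, rectum), implants of
one curved intrauterine probe plus ovoids and near-parallel needles, paired
intraoperative/planning scenarios related by a known rigid transform and known
per-needle depth shifts, and two-arm dosimetric cohort tables.

Default tissue parameters are chosen so the analytic contrast-to-noise ratios
match the cohort means observed clinically on intraoperative CBCT (about 5
between bladder and uterus and 8.5 between uterus and visceral fat); the
default effect preset for cohorts mirrors the reported cohort-level changes
(V100 97.2→98.7 %, D90 111→117 %, bladder D2ccm 64→65 %, rectum 42→37 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import VoxelGrid
from .tracks import ApplicatorTrack, RigidTransform

SOFT_TISSUE_CLASSES = ("uterus", "bladder", "fat", "background")
TISSUE_CLASSES = SOFT_TISSUE_CLASSES + ("bone", "applicator")


@dataclass
class TissueModel:
    """Per-class HU populations plus global imaging noise.

    ``class_sd`` models textural tissue variability, ``noise_sd`` the CBCT
    imaging noise; voxel HU within a class is the class mean plus independent
    Gaussian draws from both. The effective ROI standard deviation is therefore
    sqrt(class_sd^2 + noise_sd^2).
    """

    means: dict = field(
        default_factory=lambda: {
            "uterus": 45.0,
            "bladder": -35.0,
            "fat": -91.0,
            "background": 20.0,
            "bone": 700.0,
            "applicator": 1200.0,
        }
    )
    sds: dict = field(
        default_factory=lambda: {
            "uterus": 5.0,
            "bladder": 5.0,
            "fat": 5.0,
            "background": 5.0,
            "bone": 30.0,
            "applicator": 30.0,
        }
    )
    noise_sd: float = 15.2
    artifact: bool = False
    artifact_amplitude: float = 40.0

    def __post_init__(self) -> None:
        missing = set(TISSUE_CLASSES) - set(self.means) | set(TISSUE_CLASSES) - set(self.sds)
        if missing:
            raise ValueError(f"tissue model missing classes: {sorted(missing)}")
        if any(sd < 0 for sd in self.sds.values()) or self.noise_sd < 0:
            raise ValueError("class SDs and noise SD must be >= 0")
        soft_max = max(self.means[c] for c in SOFT_TISSUE_CLASSES)
        if self.means["applicator"] - soft_max < 200.0:
            raise ValueError(
                "applicator mean must exceed every soft-tissue mean by >= 200 HU "
                "so that profile peaks are detectable by construction"
            )

    def effective_sd(self, tissue: str) -> float:
        return float(np.hypot(self.sds[tissue], self.noise_sd))

    def analytic_cnr(self, tissue_x: str, tissue_y: str) -> float:
        """Population CNR |mu_x - mu_y| / sqrt((sigma_x^2 + sigma_y^2)/2)."""
        sx, sy = self.effective_sd(tissue_x), self.effective_sd(tissue_y)
        return abs(self.means[tissue_x] - self.means[tissue_y]) / np.sqrt(
            (sx**2 + sy**2) / 2.0
        )


@dataclass
class ImplantSpec:
    """Geometry of one intrauterine probe, 0-2 ovoids and 0-8 needles.

    The probe is a planar unit-speed curve whose curvature varies linearly
    along arc length (``curvature + curvature_gradient * s``); needles are
    straight, mutually parallel, and equally spaced along x, inserted from the
    entry plane z = 0 along ``insertion_dir`` (+z = cranial by default).
    """

    probe_length: float = 55.0
    probe_curvature: float = 0.004
    probe_curvature_gradient: float = 5e-5
    ovoid_count: int = 2
    ovoid_standoff: float = 12.0
    ovoid_length: float = 20.0
    needle_count: int = 4
    needle_spacing: float = 10.0
    needle_depths: tuple = (52.0,)
    insertion_dir: tuple = (0.0, 0.0, 1.0)
    needle_lateral_offset: float = 7.0

    def __post_init__(self) -> None:
        if self.probe_length <= 0:
            raise ValueError("probe length must be positive")
        if self.needle_spacing <= 0:
            raise ValueError("needle spacing must be positive")
        if not 0 <= self.ovoid_count <= 2:
            raise ValueError("ovoid count must be 0-2")
        if not 0 <= self.needle_count <= 8:
            raise ValueError("needle count must be 0-8")
        d = np.asarray(self.insertion_dir, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("insertion direction must have unit norm")
        depths = self.depths_per_needle()
        if np.any(depths < 0):
            raise ValueError("needle depths must be >= 0")

    def depths_per_needle(self) -> np.ndarray:
        depths = np.asarray(self.needle_depths, dtype=float)
        if depths.size == 1:
            depths = np.full(self.needle_count, depths.item())
        if depths.size != self.needle_count:
            raise ValueError(
                f"{depths.size} depths given for {self.needle_count} needles"
            )
        return depths


@dataclass
class ScenarioTruth:
    """Recorded ground truth of one synthetic scenario (bit-reproducible)."""

    tissue: TissueModel = field(default_factory=TissueModel)
    implant: ImplantSpec = field(default_factory=ImplantSpec)
    transform: RigidTransform = field(default_factory=RigidTransform.identity)
    depth_shifts: tuple = (0.0,)
    prescription_gy: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        shifts = np.asarray(self.depth_shifts, dtype=float)
        if shifts.size == 1:
            shifts = np.full(self.implant.needle_count, shifts.item())
        if shifts.size != self.implant.needle_count:
            raise ValueError("one depth shift per needle required")
        self.depth_shifts = tuple(shifts.tolist())


# --- implant generation ---------------------------------------------------


def _probe_curve(spec: ImplantSpec, recon_step: float = 2.0) -> np.ndarray:
    """Integrate the planar probe curve; returns base-first points (z up)."""
    fine = 0.02
    n = int(np.ceil(spec.probe_length / fine))
    s = np.linspace(0.0, spec.probe_length, n + 1)
    theta = spec.probe_curvature * s + 0.5 * spec.probe_curvature_gradient * s**2
    # unit-speed planar curve in the x-z plane, starting upward (+z)
    dz = np.cos(theta)
    dx = np.sin(theta)
    x = np.concatenate([[0.0], np.cumsum((dx[1:] + dx[:-1]) / 2 * np.diff(s))])
    z = np.concatenate([[0.0], np.cumsum((dz[1:] + dz[:-1]) / 2 * np.diff(s))])
    pts = np.column_stack([x, np.zeros_like(x), z])
    keep = np.searchsorted(s, np.arange(0.0, spec.probe_length, recon_step))
    keep = np.unique(np.append(keep, n))
    return pts[keep]


def generate_implant(spec: ImplantSpec) -> list[ApplicatorTrack]:
    """Build the applicator tracks of an implant in the implant frame.

    The probe base sits at the origin with the tip cranial; needle entry
    points lie in the z = 0 plane and tips at their insertion depths. All
    tracks are ordered tip first.
    """
    tracks: list[ApplicatorTrack] = []
    probe_pts = _probe_curve(spec)[::-1]  # tip first
    tracks.append(ApplicatorTrack(probe_pts, "probe", "probe"))

    d = np.asarray(spec.insertion_dir, dtype=float)
    for i in range(spec.ovoid_count):
        side = -1.0 if i == 0 else 1.0
        base = np.array([side * spec.ovoid_standoff, 0.0, -spec.ovoid_length])
        tip = np.array([side * spec.ovoid_standoff, 0.0, 0.0])
        # slight inward bow so the ovoid course is not degenerate-collinear
        mid = 0.5 * (base + tip) + np.array([-side * 1.5, 0.0, 0.0])
        pts = np.vstack([tip, 0.5 * (tip + mid), mid, 0.5 * (mid + base), base])
        tracks.append(ApplicatorTrack(pts, "ovoid", f"ovoid_{'LR'[i]}"))

    depths = spec.depths_per_needle()
    x0 = -(spec.needle_count - 1) / 2.0 * spec.needle_spacing
    for k in range(spec.needle_count):
        entry = np.array([x0 + k * spec.needle_spacing, spec.needle_lateral_offset, 0.0])
        if depths[k] <= 0:
            raise ValueError(f"needle {k} has zero length")
        tip = entry + depths[k] * d
        n_pts = max(2, int(np.ceil(depths[k] / 5.0)) + 1)
        frac = np.linspace(1.0, 0.0, n_pts)[:, None]
        pts = entry + frac * (tip - entry)
        tracks.append(ApplicatorTrack(pts, "plastic_needle", f"needle_{k}"))
    return tracks


def needle_tracks(tracks: list[ApplicatorTrack]) -> list[ApplicatorTrack]:
    return [t for t in tracks if t.kind in ("plastic_needle", "metal_needle")]


def make_scenario_pair(
    truth: ScenarioTruth, jitter_sd: float = 0.0
) -> tuple[list[ApplicatorTrack], list[ApplicatorTrack]]:
    """Build the (intraoperative, planning) implant pair for one scenario.

    The intraoperative implant is the implant after CBCT-based adjustment
    (needles at their final depths). The planning-frame implant represents the
    situation before adjustment seen on the first scan, mapped by the true
    rigid transform: each needle is retracted by its recorded depth shift
    (positive shift = needle sits deeper on the final scan, i.e. the ground
    truth EID), the whole implant is transformed, and optional Gaussian jitter
    of ``jitter_sd`` mm is added per point.
    """
    rng = np.random.default_rng(truth.seed + 1)
    intraop = generate_implant(truth.implant)
    d = np.asarray(truth.implant.insertion_dir, dtype=float)
    planning: list[ApplicatorTrack] = []
    needle_idx = 0
    for trk in intraop:
        pts = trk.points.copy()
        if trk.kind in ("plastic_needle", "metal_needle"):
            pts = pts - truth.depth_shifts[needle_idx] * d
            needle_idx += 1
        pts = truth.transform.apply(pts)
        if jitter_sd > 0:
            pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
        planning.append(ApplicatorTrack(pts, trk.kind, trk.name))
    return intraop, planning


# --- phantom volume -------------------------------------------------------


@dataclass
class PhantomGeometry:
    """Ellipsoid centres/semi-axes in mm; defaults scale with the volume extent."""

    fat_center: np.ndarray
    fat_semi: np.ndarray
    uterus_center: np.ndarray
    uterus_semi: np.ndarray
    hrctv_center: np.ndarray
    hrctv_semi: np.ndarray
    bladder_center: np.ndarray
    bladder_semi: np.ndarray
    rectum_center: np.ndarray
    rectum_semi: np.ndarray
    bone_semi: np.ndarray
    bone_offset_x: float
    implant_origin: np.ndarray

    @classmethod
    def proportional(cls, extent: np.ndarray) -> "PhantomGeometry":
        e = np.asarray(extent, dtype=float)
        c = e / 2.0
        return cls(
            fat_center=c,
            fat_semi=0.40 * e,
            uterus_center=c + e * np.array([0.0, -0.03, 0.05]),
            uterus_semi=e * np.array([0.17, 0.14, 0.20]),
            hrctv_center=c + e * np.array([0.0, -0.03, 0.065]),
            hrctv_semi=e * np.array([0.125, 0.09, 0.14]),
            bladder_center=c + e * np.array([0.0, -0.27, -0.05]),
            bladder_semi=e * np.array([0.125, 0.10, 0.115]),
            rectum_center=c + e * np.array([0.0, 0.22, -0.07]),
            rectum_semi=e * np.array([0.07, 0.07, 0.17]),
            bone_semi=e * np.array([0.07, 0.20, 0.31]),
            bone_offset_x=0.39 * float(e[0]),
            implant_origin=c + e * np.array([0.0, -0.03, -0.20]),
        )


def _ellipsoid_mask(grid: VoxelGrid, center, semi) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=float)
    world = [grid.origin[a] + idx[a] * grid.spacing[a] for a in range(3)]
    q = sum(((world[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return q <= 1.0


def _check_fits(name: str, center, semi, lo, hi) -> None:
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semi, dtype=float)
    if np.any(center - semi < lo) or np.any(center + semi > hi):
        raise ValueError(
            f"structure {name!r} (center {center}, semi-axes {semi}) does not fit "
            f"inside the volume bounds [{lo}, {hi}] mm; enlarge the volume or "
            f"shrink the structure"
        )


def generate_phantom_volume(
    truth: ScenarioTruth,
    shape: tuple = (128, 128, 128),
    spacing: float = 1.0,
    geometry: PhantomGeometry | None = None,
    tracks: list[ApplicatorTrack] | None = None,
    applicator_radius: float = 1.0,
) -> tuple[VoxelGrid, dict]:
    """Generate the HU phantom volume and its structure masks.

    Returns ``(volume, masks)`` where ``masks`` maps ``hrctv``, ``bladder``,
    ``rectum``, ``bone`` and ``applicator`` to binary :class:`VoxelGrid` masks
    on the same geometry. Identical ``truth.seed`` gives an identical volume.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError(f"shape must be at least 32^3, got {shape}")
    grid = VoxelGrid(np.zeros(shape), spacing, np.zeros(3))
    extent = grid.extent_mm()
    geo = geometry or PhantomGeometry.proportional(extent)

    lo, hi = np.zeros(3), extent
    for nm in ("fat", "uterus", "hrctv", "bladder", "rectum"):
        _check_fits(nm, getattr(geo, f"{nm}_center"), getattr(geo, f"{nm}_semi"), lo, hi)
    for sx, nm in ((-1, "bone_left"), (1, "bone_right")):
        cb = geo.fat_center + np.array([sx * geo.bone_offset_x, 0.0, 0.0])
        _check_fits(nm, cb, geo.bone_semi, lo, hi)

    if tracks is None:
        tracks = [
            ApplicatorTrack(t.points + geo.implant_origin, t.kind, t.name)
            for t in generate_implant(truth.implant)
        ]
    for t in tracks:
        for p in (t.points[0], t.points[-1]):
            if not grid.contains_point(p):
                raise ValueError(
                    f"applicator {t.name!r} endpoint {p} lies outside the "
                    f"volume (extent {extent} mm); shorten the implant or "
                    f"enlarge the volume"
                )

    labels = np.zeros(shape, dtype=np.uint8)  # 0=background
    class_of_label = {
        0: "background", 1: "fat", 2: "uterus", 3: "bladder",
        4: "background", 5: "bone", 6: "applicator",
    }
    labels[_ellipsoid_mask(grid, geo.fat_center, geo.fat_semi)] = 1
    uterus = _ellipsoid_mask(grid, geo.uterus_center, geo.uterus_semi)
    labels[uterus] = 2
    bladder = _ellipsoid_mask(grid, geo.bladder_center, geo.bladder_semi)
    labels[bladder] = 3
    rectum = _ellipsoid_mask(grid, geo.rectum_center, geo.rectum_semi)
    labels[rectum] = 4
    bone = np.zeros(shape, dtype=bool)
    for sx in (-1, 1):
        cb = geo.fat_center + np.array([sx * geo.bone_offset_x, 0.0, 0.0])
        bone |= _ellipsoid_mask(grid, cb, geo.bone_semi)
    labels[bone] = 5

    applicator = np.zeros(shape, dtype=bool)
    for t in tracks:
        fine = t.resampled(min(0.2, spacing / 2))
        idx = np.rint(grid.world_to_index(fine.points)).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        r_vox = max(1, int(np.ceil(applicator_radius / spacing)))
        offs = np.indices((2 * r_vox + 1,) * 3).reshape(3, -1).T - r_vox
        offs = offs[np.linalg.norm(offs * spacing, axis=1) <= applicator_radius + 1e-9]
        all_idx = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        all_idx = np.clip(all_idx, 0, np.asarray(shape) - 1)
        applicator[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]] = True
    labels[applicator] = 6

    rng = np.random.default_rng(truth.seed)
    tm = truth.tissue
    mean_lut = np.array([tm.means[class_of_label[l]] for l in range(7)])
    sd_lut = np.array([tm.sds[class_of_label[l]] for l in range(7)])
    hu = mean_lut[labels]
    hu = hu + sd_lut[labels] * rng.standard_normal(shape)
    if tm.noise_sd > 0:
        hu = hu + tm.noise_sd * rng.standard_normal(shape)
    if tm.artifact:
        # low-frequency sinusoidal streak stand-in (stress input only)
        idx = np.indices(shape, dtype=float)
        phase = 2 * np.pi * (idx[0] / shape[0] * 3 + idx[1] / shape[1] * 2)
        hu = hu + tm.artifact_amplitude * np.sin(phase)

    hrctv = uterus & _ellipsoid_mask(grid, geo.hrctv_center, geo.hrctv_semi)
    masks = {
        "hrctv": grid.like(hrctv.astype(np.uint8)),
        "bladder": grid.like(bladder.astype(np.uint8)),
        "rectum": grid.like(rectum.astype(np.uint8)),
        "bone": grid.like(bone.astype(np.uint8)),
        "applicator": grid.like(applicator.astype(np.uint8)),
    }
    return grid.like(hu), masks


def suggested_rois(grid: VoxelGrid, geometry: PhantomGeometry | None = None,
                   radius_mm: float = 5.0) -> list:
    """Circular ROIs inside uterus, bladder and visceral fat, clear of
    applicators and bone, derived from the phantom geometry."""
    from .image_quality import ROISpec

    geo = geometry or PhantomGeometry.proportional(grid.extent_mm())
    k_ut = int(np.rint((geo.uterus_center[2] - grid.origin[2]) / grid.spacing[2]))
    k_bl = int(np.rint((geo.bladder_center[2] - grid.origin[2]) / grid.spacing[2]))
    # fat sits between the lateral bone and the uterus
    x_lo = geo.fat_center[0] - geo.bone_offset_x + geo.bone_semi[0]
    x_hi = geo.uterus_center[0] - geo.uterus_semi[0]
    fat_r = min(radius_mm, (x_hi - x_lo) / 2.0 - 1.0)
    return [
        ROISpec(k_ut, (geo.uterus_center[0] - 12.0, geo.uterus_center[1]),
                radius_mm, "uterus"),
        ROISpec(k_bl, (geo.bladder_center[0], geo.bladder_center[1]),
                radius_mm, "bladder"),
        ROISpec(k_ut, ((x_lo + x_hi) / 2.0, geo.fat_center[1]), fat_r, "fat"),
    ]


# --- dosimetric cohorts ---------------------------------------------------

#: Baseline ("previous" workflow) metric distributions: mean and SD in % of
#: the prescription (doses) or of the structure volume (V100).
COHORT_BASELINE = {
    "v100": (97.2, 2.5),
    "d90": (111.0, 5.0),
    "d2ccm_bladder": (64.0, 14.0),
    "d2ccm_rectum": (42.0, 14.0),
}

#: Cohort-level effect of the CBCT-guided workflow on the arm means.
PAPER_EFFECT = {"v100": 1.5, "d90": 6.0, "d2ccm_bladder": 1.0, "d2ccm_rectum": -5.0}

METRIC_COLUMNS = tuple(COHORT_BASELINE)


def generate_cohort(
    n_patients: int,
    effect: dict | None = None,
    seed: int = 0,
    baseline: dict | None = None,
    arms: tuple = ("previous", "new"),
) -> pd.DataFrame:
    """Two-arm dosimetric cohort table with ``n_patients`` per arm.

    With ``effect`` empty (all offsets zero) the two arms are exchangeable
    draws from the same baseline distributions.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients per arm")
    effect = dict(effect or {})
    base = dict(baseline or COHORT_BASELINE)
    rng = np.random.default_rng(seed)
    rows = []
    for arm_i, arm in enumerate(arms):
        for p in range(n_patients):
            rec = {"patient_id": f"{arm}_{p:03d}", "arm": arm}
            for metric, (mu, sd) in base.items():
                shift = effect.get(metric, 0.0) if arm_i == 1 else 0.0
                rec[metric] = mu + shift + sd * rng.standard_normal()
            rec["ratio_bladder"] = rec["d2ccm_bladder"] / rec["d90"]
            rec["ratio_rectum"] = rec["d2ccm_rectum"] / rec["d90"]
            rows.append(rec)
    return pd.DataFrame(rows)
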