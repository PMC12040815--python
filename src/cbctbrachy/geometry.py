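"""Implant-geometry analyses: probe ICP registration, MAE, EID, border distance.

Applicator courses digitized on two scans are compared by (i) resampling every
track to 0.5 mm arc-length spacing from the tip, (ii) rigidly registering the
intrauterine probe of one scan to the other with a point-to-point iterative
closest point (ICP) algorithm, and (iii) reporting the mean absolute error
(mean Euclidean distance between index-corresponded resampled points) of the
remaining applicators under that registration. The enhanced insertion depth
(EID) of a needle between a first and last scan is the signed tip displacement:
positive when the needle was shifted deeper along the insertion direction,
negative when retracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids import VoxelGrid
from .tracks import ApplicatorTrack, RigidTransform

RESAMPLE_STEP_MM = 0.5


def resample_track(track: ApplicatorTrack, step: float = RESAMPLE_STEP_MM) -> ApplicatorTrack:
    """Resample a track at equidistant arc-length steps from the tip."""
    return track.resampled(step)


def mae(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Mean Euclidean distance between index-corresponded point sets (mm)."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"point sets must correspond index-wise, got shapes {a.shape} and "
            f"{b.shape}; resample both tracks to a common count from the tip"
        )
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def corresponding_mae(track_a: ApplicatorTrack, track_b: ApplicatorTrack,
                      step: float = RESAMPLE_STEP_MM) -> float:
    """MAE between two tracks resampled from the tip at a common step.

    Both curves are corresponded by arc-length index; the shorter curve
    truncates both to a common point count.
    """
    ra = resample_track(track_a, step).points
    rb = resample_track(track_b, step).points
    n = min(len(ra), len(rb))
    return mae(ra[:n], rb[:n])


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mae_trace: np.ndarray  # nearest-neighbour MAE after each iteration, mm
    converged: bool
    iterations: int
    degenerate: bool = False  # collinear point set: rotation about the line axis unconstrained

    def __post_init__(self) -> None:
        self.mae_trace = np.asarray(self.mae_trace, dtype=float)
        if np.any(np.diff(self.mae_trace) > 1e-12):
            raise AssertionError("MAE trace must be non-increasing")

    @property
    def final_mae(self) -> float:
        return float(self.mae_trace[-1])


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit mapping src onto dst (SVD)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cd - rot @ cs)


def _principal_axes(points: np.ndarray, tip: np.ndarray) -> np.ndarray:
    """Right-handed principal frame with signs fixed by tip and third moment."""
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1].T.copy()  # rows, descending variance
    if axes[0] @ (tip - c) < 0:
        axes[0] = -axes[0]
    skew = np.sum(((points - c) @ axes[1]) ** 3)
    ref = skew if abs(skew) > 1e-9 else axes[1] @ (tip - c)
    if ref < 0:
        axes[1] = -axes[1]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def _nn_mae(tree: cKDTree, pts: np.ndarray) -> float:
    d, _ = tree.query(pts)
    return float(np.mean(d))


def _icp_once(moving: np.ndarray, fixed: np.ndarray, tree: cKDTree,
              init: RigidTransform, tol: float, max_iter: int):
    transform = init
    cur = init.apply(moving)
    trace = [_nn_mae(tree, cur)]
    converged = False
    for _ in range(max_iter):
        _, idx = tree.query(cur)
        candidate = _kabsch(moving, fixed[idx])
        new_pts = candidate.apply(moving)
        new_mae = _nn_mae(tree, new_pts)
        if new_mae > trace[-1]:          # would worsen the MAE: keep previous
            converged = True
            break
        improved = trace[-1] - new_mae
        transform, cur = candidate, new_pts
        trace.append(new_mae)
        if improved < tol:
            converged = True
            break
    return transform, np.asarray(trace), converged


def icp_register(
    moving: ApplicatorTrack | np.ndarray,
    fixed: ApplicatorTrack | np.ndarray,
    tol_mm: float = 1e-6,
    max_iterations: int = 200,
) -> RegistrationResult:
    """Point-to-point ICP rigid registration of a moving track onto a fixed one.

    Correspondences are nearest neighbours; each iteration refits the rigid
    transform in closed form (SVD). Initialization aligns centroids and
    principal axes (two rotational starts to resolve the 180-degree axis
    ambiguity; the start with the lower final MAE wins). The recorded MAE
    trace is non-increasing: an update that would increase the nearest-
    neighbour MAE is rejected and iteration stops.
    """
    mpts = moving.points if isinstance(moving, ApplicatorTrack) else np.asarray(moving, float)
    fpts = fixed.points if isinstance(fixed, ApplicatorTrack) else np.asarray(fixed, float)
    mtip = mpts[0]
    ftip = fpts[0]
    tree = cKDTree(fpts)

    cov = np.cov((mpts - mpts.mean(axis=0)).T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    degenerate = evals[1] < 1e-12 * max(evals[2], 1.0)
    if degenerate:
        warnings.warn(
            "collinear point set: rotation about the line axis is unconstrained",
            stacklevel=2,
        )

    am = _principal_axes(mpts, mtip)
    af = _principal_axes(fpts, ftip)
    inits = []
    for flip in (1.0, -1.0):
        axes = am.copy()
        axes[1] *= flip
        axes[2] = np.cross(axes[0], axes[1])
        rot = af.T @ axes
        t = fpts.mean(axis=0) - rot @ mpts.mean(axis=0)
        inits.append(RigidTransform(rot, t))

    best = None
    for init in inits:
        transform, trace, converged = _icp_once(
            mpts, fpts, tree, init, tol_mm, max_iterations
        )
        if best is None or trace[-1] < best[1][-1]:
            best = (transform, trace, converged)
    transform, trace, converged = best
    return RegistrationResult(transform, trace, converged, len(trace) - 1, degenerate)


def eid(tip_last: np.ndarray, tip_first: np.ndarray, insertion_dir: np.ndarray) -> float:
    """Enhanced insertion depth: signed tip displacement between two scans.

    Magnitude is the Euclidean distance between the tip on the last scan (A)
    and on the first scan (B), both in the same coordinate frame. The sign is
    positive if the needle was shifted deeper (the displacement projects
    non-negatively onto the insertion direction), negative if retracted.
    """
    a = np.asarray(tip_last, dtype=float)
    b = np.asarray(tip_first, dtype=float)
    d = np.asarray(insertion_dir, dtype=float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
        raise ValueError("insertion direction must have unit norm")
    magnitude = float(np.linalg.norm(a - b))
    sign = 1.0 if (a - b) @ d >= 0.0 else -1.0
    return sign * magnitude


@dataclass
class TipBorderResult:
    """Needle tip vs cranial HR-CTV border along the implantation direction."""

    status: str  # "measured" | "reaches_border" | "misses_target"
    distance_mm: float | None = None


def tip_to_border_distance(
    needle: ApplicatorTrack,
    hrctv_mask: VoxelGrid,
    march_step_mm: float = 0.05,
    max_distance_mm: float = 200.0,
) -> TipBorderResult:
    """Distance from a needle tip to the cranial HR-CTV border along its tangent.

    A needle whose tip lies inside the target or at/cranial to the cranial
    border plane (the plane tangent to the mask at its maximum z) "reaches the
    border" and no distance is reported. Otherwise a ray is marched from the
    tip along the tip tangent in ``march_step_mm`` steps; the distance to the
    first mask entry is returned (sub-voxel position by the midpoint of the
    bracketing steps). A ray that never enters the mask "misses the target".
    """
    if not np.any(hrctv_mask.data > 0.5):
        raise ValueError("HR-CTV mask is empty")
    tip = needle.tip
    direction = needle.tip_tangent
    idx_z = np.argwhere(hrctv_mask.data > 0.5)[:, 2]
    border_z = hrctv_mask.origin[2] + idx_z.max() * hrctv_mask.spacing[2]
    inside = hrctv_mask.sample_nearest(tip[None, :])[0] > 0.5
    if inside or tip[2] >= border_z - 1e-9:
        return TipBorderResult("reaches_border")
    n_steps = int(np.ceil(max_distance_mm / march_step_mm))
    s = np.arange(1, n_steps + 1) * march_step_mm
    pts = tip[None, :] + s[:, None] * direction[None, :]
    in_bounds = np.all(
        (pts >= hrctv_mask.origin - hrctv_mask.spacing / 2)
        & (pts <= hrctv_mask.origin + (np.asarray(hrctv_mask.shape) - 0.5) * hrctv_mask.spacing),
        axis=1,
    )
    hits = np.zeros(len(s), dtype=bool)
    if np.any(in_bounds):
        hits[in_bounds] = hrctv_mask.sample_nearest(pts[in_bounds]) > 0.5
    if not np.any(hits):
        return TipBorderResult("misses_target")
    first = int(np.argmax(hits))
    entry = s[first] - march_step_mm / 2.0 if first > 0 else s[first] / 2.0
    return TipBorderResult("measured", float(entry))
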