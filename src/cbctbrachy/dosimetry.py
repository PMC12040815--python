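"""Point-source Ir-192 dose engine, dwell placement, DVH metrics, virtual shift.

The dose engine follows the TG-43 point-source form: dose at distance r from a
dwell is ``time * rate * (10/r)^2 * g(r) * F(r)`` with the radial dose function
g normalized to g(10 mm) = 1 and an optional anisotropy factor F (default 1).
g defaults to 1, which keeps every geometric comparison analytic; a consensus
table can be supplied. All cohort-level dose results are reported relative to
the prescription, so the absolute scale of the engine cancels out.

Dwell positions step along each applicator channel at 2.5 mm, starting at the
applicator-specific tip offset (6 mm for intrauterine probes/ovoids, 5 mm for
plastic and 9 mm for metal needles): the first possible source position sits
that far behind the physical tip by applicator design. The virtual needle-shift
simulation retracts a needle by editing this reconstruction offset exactly as
a treatment planning system would (a plastic needle retracted by 10 mm gets an
offset of -15 mm), which is equivalent to translating its dwells caudally
along the track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .grids import VoxelGrid
from .tracks import ApplicatorTrack

#: Distance from the physical applicator tip to the first possible dwell (mm).
DEFAULT_TIP_OFFSETS = {
    "probe": 6.0,
    "ovoid": 6.0,
    "plastic_needle": 5.0,
    "metal_needle": 9.0,
}

#: Planning-system reconstruction offsets (negative of the tip offsets).
PLANNING_OFFSETS = {"plastic_needle": -5.0, "metal_needle": -9.0}

STEP_SIZE_MM = 2.5


@dataclass
class SourceModel:
    """TG-43-style point-source model of a stepping Ir-192 source."""

    reference_rate: float = 1.0  # dose per unit dwell time at 10 mm
    radial_table_r_mm: np.ndarray | None = None
    radial_table_g: np.ndarray | None = None
    anisotropy_table_r_mm: np.ndarray | None = None
    anisotropy_table_f: np.ndarray | None = None
    step_mm: float = STEP_SIZE_MM
    min_radius_mm: float = 0.5  # near-field clamp against the 1/r^2 singularity

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step size must be positive")
        if self.min_radius_mm <= 0:
            raise ValueError("near-field clamp radius must be positive")
        if (self.radial_table_r_mm is None) != (self.radial_table_g is None):
            raise ValueError("radial table needs both radii and g values")
        if self.radial_table_r_mm is not None:
            r = np.asarray(self.radial_table_r_mm, dtype=float)
            g = np.asarray(self.radial_table_g, dtype=float)
            if np.any(g <= 0):
                raise ValueError("g(r) must be positive")
            if not np.isclose(np.interp(10.0, r, g), 1.0, atol=1e-6):
                raise ValueError("radial dose function must satisfy g(10 mm) = 1")
            self.radial_table_r_mm, self.radial_table_g = r, g

    def g(self, r_mm: np.ndarray) -> np.ndarray:
        if self.radial_table_r_mm is None:
            return np.ones_like(np.asarray(r_mm, dtype=float))
        return np.interp(r_mm, self.radial_table_r_mm, self.radial_table_g)

    def anisotropy(self, r_mm: np.ndarray) -> np.ndarray:
        if self.anisotropy_table_r_mm is None:
            return np.ones_like(np.asarray(r_mm, dtype=float))
        return np.interp(r_mm, self.anisotropy_table_r_mm, self.anisotropy_table_f)


@dataclass
class DwellChannel:
    """Dwell positions and times of one applicator channel."""

    track_name: str
    kind: str
    tip_offset_mm: float
    arc_positions_mm: np.ndarray  # arc length from the physical tip
    positions: np.ndarray  # (n, 3) world mm
    times: np.ndarray  # dwell times, >= 0

    def __post_init__(self) -> None:
        self.arc_positions_mm = np.asarray(self.arc_positions_mm, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0):
            raise ValueError("dwell times must be non-negative")
        if self.arc_positions_mm.size:
            if not np.isclose(self.arc_positions_mm[0], self.tip_offset_mm):
                raise ValueError("first dwell must sit at the tip offset")


@dataclass
class DwellSet:
    channels: list = field(default_factory=list)

    @property
    def all_positions(self) -> np.ndarray:
        if not self.channels:
            return np.zeros((0, 3))
        return np.vstack([c.positions for c in self.channels if len(c.positions)])

    @property
    def all_times(self) -> np.ndarray:
        if not self.channels:
            return np.zeros(0)
        return np.concatenate([c.times for c in self.channels if len(c.times)])

    def with_times(self, times: np.ndarray) -> "DwellSet":
        """A copy with dwell times replaced from a flat vector."""
        times = np.asarray(times, dtype=float)
        out, k = [], 0
        for c in self.channels:
            n = len(c.times)
            out.append(replace(c, times=times[k:k + n].copy()))
            k += n
        if k != times.size:
            raise ValueError("time vector length mismatch")
        return DwellSet(out)

    def scaled(self, factor: float) -> "DwellSet":
        return self.with_times(self.all_times * factor)


def place_dwells(
    track: ApplicatorTrack,
    active_length_mm: float | None = None,
    step_mm: float = STEP_SIZE_MM,
    tip_offset_mm: float | None = None,
    default_time: float = 1.0,
) -> DwellChannel:
    """Place dwells along a track at the source step size from the tip offset.

    Dwells sit at arc lengths ``offset, offset + step, ...`` from the physical
    tip, up to the smaller of the active length and the track length; 3D
    positions follow the polyline by arc-length interpolation. A track shorter
    than its tip offset yields zero dwells (flagged with a warning).
    """
    offset = DEFAULT_TIP_OFFSETS[track.kind] if tip_offset_mm is None else tip_offset_mm
    limit = track.length if active_length_mm is None else min(active_length_mm, track.length)
    if offset > limit + 1e-9:
        warnings.warn(
            f"track {track.name!r} ({track.length:.1f} mm) shorter than its tip "
            f"offset ({offset:.1f} mm): no dwell positions available",
            stacklevel=2,
        )
        return DwellChannel(track.name, track.kind, offset,
                            np.zeros(0), np.zeros((0, 3)), np.zeros(0))
    n = int(np.floor((limit - offset) / step_mm + 1e-9)) + 1
    arcs = offset + step_mm * np.arange(n)
    pts = np.atleast_2d(track.point_at_arc_length(arcs))
    return DwellChannel(track.name, track.kind, offset, arcs, pts,
                        np.full(n, default_time))


def plan_dwells(tracks, active_length_mm: float | None = None,
                step_mm: float = STEP_SIZE_MM) -> DwellSet:
    """Place dwells on every track of an implant with default tip offsets."""
    return DwellSet([place_dwells(t, active_length_mm, step_mm) for t in tracks])


def virtual_shift_offset(
    applicator_type: str,
    retraction_mm: float,
    default_offsets: dict | None = None,
) -> float:
    """Planning-system offset realizing a virtual caudal needle retraction.

    The reconstruction offset of a needle is negative by design (first dwell
    behind the tip). Retracting a needle virtually by ``retraction_mm`` in the
    caudal direction subtracts the retraction from the default offset: a
    plastic needle (default -5 mm) retracted by 10 mm gets -15 mm. A negative
    retraction (deeper virtual shift) adds to the offset instead.
    """
    offsets = PLANNING_OFFSETS if default_offsets is None else default_offsets
    if applicator_type not in offsets:
        raise KeyError(
            f"no planning offset defined for {applicator_type!r}; "
            f"known: {sorted(offsets)}"
        )
    return offsets[applicator_type] - retraction_mm


def apply_virtual_shift(
    track: ApplicatorTrack,
    retraction_mm: float,
    active_length_mm: float | None = None,
    step_mm: float = STEP_SIZE_MM,
) -> DwellChannel:
    """Dwell placement for a virtually retracted needle via its offset.

    Equivalent to translating the dwells ``retraction_mm`` caudally along the
    track: the adjusted tip offset is the default tip offset plus the
    retraction. Falls back to zero dwells (flagged) if the adjusted first
    dwell falls off the track.
    """
    tip_offset = DEFAULT_TIP_OFFSETS[track.kind] + retraction_mm
    if tip_offset < 0:
        raise ValueError("virtual shift would place the first dwell beyond the tip")
    return place_dwells(track, active_length_mm, step_mm, tip_offset_mm=tip_offset)


# --- dose computation -----------------------------------------------------


def dose_at_points(dwells: DwellSet, source: SourceModel, points: np.ndarray,
                   chunk: int = 200_000) -> np.ndarray:
    """Total dose at world positions (n, 3); linear in dwell times."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pos = dwells.all_positions
    times = dwells.all_times
    out = np.zeros(len(pts))
    if len(pos) == 0:
        return out
    for start in range(0, len(pts), chunk):
        block = pts[start:start + chunk]
        r = np.linalg.norm(block[:, None, :] - pos[None, :, :], axis=2)
        r = np.maximum(r, source.min_radius_mm)
        contrib = (
            times[None, :]
            * source.reference_rate
            * (10.0 / r) ** 2
            * source.g(r)
            * source.anisotropy(r)
        )
        out[start:start + chunk] = contrib.sum(axis=1)
    return out


def dose_at_point(dwells: DwellSet, source: SourceModel, point) -> float:
    return float(dose_at_points(dwells, source, np.asarray(point, float)[None, :])[0])


def compute_dose_grid(dwells: DwellSet, source: SourceModel,
                      geometry: VoxelGrid) -> VoxelGrid:
    """Dose evaluated at every voxel centre of the given grid geometry."""
    centers = geometry.voxel_centers()
    dose = dose_at_points(dwells, source, centers)
    return geometry.like(dose.reshape(geometry.shape))


# --- optimization ---------------------------------------------------------


@dataclass
class OARConstraint:
    """Hinge penalty keeping sampled OAR doses at or below a physical limit."""

    name: str
    points: np.ndarray
    limit_dose: float
    weight: float = 10.0


def optimize_dwell_times(
    dwells: DwellSet,
    source: SourceModel,
    target_points: np.ndarray,
    prescription: float,
    oar_constraints: list | None = None,
    max_passes: int = 20,
) -> DwellSet:
    """Deterministic non-negative least-squares dwell-time optimization.

    Minimizes the squared deviation of target surface-sample doses from the
    prescription plus a weighted hinge penalty on OAR sample doses above their
    limits (a stand-in for manual forward planning). The hinge is handled by
    an active-set iteration over the OAR samples currently above their limit.
    Returns a new dwell set; if no dwell can reach the target the times are
    zero and a warning is issued.
    """
    target_points = np.atleast_2d(np.asarray(target_points, dtype=float))
    n_dwell = len(dwells.all_times)
    if n_dwell == 0 or len(target_points) == 0:
        raise ValueError("need at least one dwell and one target sample")
    unit = dwells.with_times(np.ones(n_dwell))
    a_target = _unit_dose_matrix(unit, source, target_points)
    if np.all(a_target.sum(axis=1) <= 0):
        warnings.warn("no dwell contributes dose to the target: infeasible plan",
                      stacklevel=2)
        return dwells.with_times(np.zeros(n_dwell))
    oars = oar_constraints or []
    a_oars = [_unit_dose_matrix(unit, source, np.atleast_2d(np.asarray(c.points, float)))
              for c in oars]

    b_target = np.full(len(target_points), float(prescription))
    active = [np.zeros(a.shape[0], dtype=bool) for a in a_oars]
    times = None
    for _ in range(max_passes):
        rows = [a_target]
        rhs = [b_target]
        for c, a, act in zip(oars, a_oars, active):
            if act.any():
                w = np.sqrt(c.weight)
                rows.append(w * a[act])
                rhs.append(np.full(int(act.sum()), w * c.limit_dose))
        times, _ = optimize.nnls(np.vstack(rows), np.concatenate(rhs))
        new_active = []
        for c, a in zip(oars, a_oars):
            new_active.append(a @ times > c.limit_dose * (1 + 1e-9))
        if all(np.array_equal(x, y) for x, y in zip(active, new_active)):
            break
        active = new_active
    return dwells.with_times(times)


def _unit_dose_matrix(unit_dwells: DwellSet, source: SourceModel,
                      points: np.ndarray) -> np.ndarray:
    """Matrix of per-dwell unit-time doses at the given points."""
    pos = unit_dwells.all_positions
    r = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
    r = np.maximum(r, source.min_radius_mm)
    return source.reference_rate * (10.0 / r) ** 2 * source.g(r) * source.anisotropy(r)


# --- DVH metrics ----------------------------------------------------------


@dataclass
class DVHMetrics:
    """D90, V100 and D2ccm of one structure, relative to the prescription."""

    d90_pct: float
    v100_pct: float
    d2ccm_pct: float
    volume_cm3: float
    small_structure: bool = False  # structure smaller than 2 cm^3


def dose_percentile(doses: np.ndarray, volumes: np.ndarray, volume_fraction: float) -> float:
    """Largest dose d such that at least ``volume_fraction`` of the structure
    volume receives >= d (e.g. 0.9 for D90)."""
    order = np.argsort(doses)[::-1]
    cum = np.cumsum(volumes[order])
    k = int(np.searchsorted(cum, volume_fraction * cum[-1] - 1e-12))
    return float(doses[order][min(k, len(doses) - 1)])


def dvh_metrics_from_doses(doses: np.ndarray, voxel_volume_cm3: float,
                           prescription: float,
                           hot_volume_cm3: float = 2.0) -> DVHMetrics:
    """DVH metrics from the dose values of a structure's voxels."""
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("structure has no voxels")
    volumes = np.full(doses.size, voxel_volume_cm3)
    total = float(volumes.sum())
    d90 = dose_percentile(doses, volumes, 0.9)
    v100 = float(volumes[doses >= prescription].sum() / total * 100.0)
    small = total < hot_volume_cm3
    if small:
        warnings.warn(
            f"structure volume {total:.2f} cm^3 is below {hot_volume_cm3} cm^3; "
            "reporting the minimum structure dose as D2ccm", stacklevel=2
        )
        d2 = float(doses.min())
    else:
        order = np.argsort(doses)[::-1]
        cum = np.cumsum(volumes[order])
        k = int(np.searchsorted(cum, hot_volume_cm3 - 1e-12))
        d2 = float(doses[order][min(k, doses.size - 1)])
    return DVHMetrics(
        d90_pct=d90 / prescription * 100.0,
        v100_pct=v100,
        d2ccm_pct=d2 / prescription * 100.0,
        volume_cm3=total,
        small_structure=small,
    )


def dvh_metrics(dose: VoxelGrid, mask: VoxelGrid, prescription: float,
                hot_volume_cm3: float = 2.0) -> DVHMetrics:
    """DVH metrics of a structure on a dose grid, in % of the prescription.

    D90 is the dose the most exposed 90% of the structure receives, V100 the
    percentage of the structure receiving at least the prescription, and
    D2ccm the minimum dose within the hottest 2 cm^3 (voxel-volume weighted
    whole-voxel sorting). A structure smaller than 2 cm^3 reports its minimum
    dose as D2ccm and is flagged.
    """
    if dose.shape != mask.shape:
        raise ValueError("dose and mask grids must share their geometry")
    sel = mask.data > 0.5
    if not np.any(sel):
        raise ValueError("structure mask is empty on the dose grid")
    doses = np.asarray(dose.data, dtype=float)[sel]
    return dvh_metrics_from_doses(doses, dose.voxel_volume_cm3, prescription,
                                  hot_volume_cm3)


def eqd2(total_dose_gy: float, dose_per_fraction_gy: float, alpha_beta_gy: float) -> float:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    EQD2 = D (d + alpha/beta) / (2 + alpha/beta). For pulsed dose rate the
    per-pulse dose stands in for d (incomplete-repair kinetics ignored).
    """
    if min(total_dose_gy, dose_per_fraction_gy, alpha_beta_gy) <= 0:
        raise ValueError("dose, dose per fraction and alpha/beta must be positive")
    return total_dose_gy * (dose_per_fraction_gy + alpha_beta_gy) / (2.0 + alpha_beta_gy)


def tradeoff_ratio(d2ccm: float, d90: float) -> float:
    """OAR exposure per unit target dose, D2ccm / D90 on a common dose scale."""
    if d90 <= 0:
        raise ValueError("D90 must be positive")
    return d2ccm / d90
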