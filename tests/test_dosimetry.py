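"""Dwell placement, dose engine, optimizer, DVH metrics, EQD2, virtual shift."""

import numpy as np
import pytest

import cbctbrachy as cb
from cbctbrachy.dosimetry import (
    DwellSet,
    OARConstraint,
    SourceModel,
    apply_virtual_shift,
    compute_dose_grid,
    dose_at_point,
    dose_at_points,
    dvh_metrics,
    dvh_metrics_from_doses,
    eqd2,
    optimize_dwell_times,
    place_dwells,
    plan_dwells,
    tradeoff_ratio,
    virtual_shift_offset,
)
from cbctbrachy.synthetic import ImplantSpec


def needle(length=20.0, kind="plastic_needle"):
    pts = np.array([[0.0, 0.0, length], [0.0, 0.0, 0.0]])
    return cb.ApplicatorTrack(pts, kind, "n0")


def single_dwell_set(position=(0.0, 0.0, 0.0), time=1.0):
    from cbctbrachy.dosimetry import DwellChannel

    return DwellSet([
        DwellChannel("s", "plastic_needle", 5.0, np.array([5.0]),
                     np.array([position], dtype=float), np.array([time]))
    ])


class TestPlaceDwells:
    def test_plastic_needle_dwell_arithmetic(self):
        ch = place_dwells(needle(20.0), active_length_mm=20.0)
        assert np.allclose(ch.arc_positions_mm, [5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0])
        assert len(ch.times) == 7

    def test_metal_needle_too_short_flagged(self):
        with pytest.warns(UserWarning, match="no dwell"):
            ch = place_dwells(needle(8.0, "metal_needle"))
        assert len(ch.times) == 0

    def test_curved_probe_dwells_on_polyline(self):
        probe = cb.generate_implant(ImplantSpec())[0]
        ch = place_dwells(probe)
        for arc, pos in zip(ch.arc_positions_mm, ch.positions):
            assert np.allclose(probe.point_at_arc_length(arc), pos, atol=1e-9)

    def test_offsets_by_applicator_type(self):
        probe = cb.generate_implant(ImplantSpec())[0]
        assert place_dwells(probe).arc_positions_mm[0] == 6.0
        assert place_dwells(needle(30.0)).arc_positions_mm[0] == 5.0
        assert place_dwells(needle(30.0, "metal_needle")).arc_positions_mm[0] == 9.0


class TestVirtualShift:
    def test_plastic_retraction_offsets(self):
        assert virtual_shift_offset("plastic_needle", 10.0) == -15.0
        assert virtual_shift_offset("metal_needle", 0.0) == -9.0
        assert virtual_shift_offset("plastic_needle", 14.0) == -19.0

    def test_unknown_type_rejected(self):
        with pytest.raises(KeyError, match="planning offset"):
            virtual_shift_offset("probe", 5.0)

    def test_offset_shift_equals_dwell_translation(self):
        """Editing the offset reproduces physically translated dwells."""
        trk = needle(40.0)
        shifted = apply_virtual_shift(trk, 10.0)
        manual = place_dwells(trk, tip_offset_mm=5.0 + 10.0)
        assert np.allclose(shifted.positions, manual.positions, atol=1e-12)
        # caudal translation of the default dwells along the track direction
        base = place_dwells(trk)
        translated = base.positions - 10.0 * trk.tip_tangent
        kept = translated[translated[:, 2] >= -1e-9]
        assert np.allclose(shifted.positions[: len(kept)], kept[: len(shifted.positions)], atol=1e-12)


class TestDoseEngine:
    def test_inverse_square(self):
        ds = single_dwell_set()
        src = SourceModel()
        d1 = dose_at_point(ds, src, (8.0, 0.0, 0.0))
        d2 = dose_at_point(ds, src, (16.0, 0.0, 0.0))
        assert d2 == pytest.approx(d1 / 4.0)

    def test_reference_condition_at_10mm(self):
        ds = single_dwell_set()
        src = SourceModel(reference_rate=2.5)
        assert dose_at_point(ds, src, (10.0, 0.0, 0.0)) == pytest.approx(2.5)

    def test_superposition_of_symmetric_dwells(self):
        from cbctbrachy.dosimetry import DwellChannel

        two = DwellSet([
            DwellChannel("a", "plastic_needle", 5.0, np.array([5.0]),
                         np.array([[-7.0, 0.0, 0.0]]), np.array([1.0])),
            DwellChannel("b", "plastic_needle", 5.0, np.array([5.0]),
                         np.array([[7.0, 0.0, 0.0]]), np.array([1.0])),
        ])
        src = SourceModel()
        single = dose_at_point(single_dwell_set((7.0, 0.0, 0.0)), src, (0.0, 0.0, 0.0))
        assert dose_at_point(two, src, (0.0, 0.0, 0.0)) == pytest.approx(2 * single)

    def test_near_field_clamp(self):
        ds = single_dwell_set()
        src = SourceModel()
        at_clamp = dose_at_point(ds, src, (src.min_radius_mm / 10, 0.0, 0.0))
        assert at_clamp == pytest.approx(dose_at_point(ds, src, (src.min_radius_mm, 0.0, 0.0)))

    def test_radial_table_validation(self):
        with pytest.raises(ValueError, match="g.10 mm."):
            SourceModel(radial_table_r_mm=np.array([1.0, 100.0]),
                        radial_table_g=np.array([2.0, 2.0]))

    def test_grid_linearity_in_times(self):
        tracks = cb.generate_implant(ImplantSpec(needle_count=2, ovoid_count=0))
        dwells = plan_dwells(tracks)
        src = SourceModel()
        geom = cb.VoxelGrid(np.zeros((20, 20, 20)), 3.0, (-30.0, -30.0, -10.0))
        d1 = compute_dose_grid(dwells, src, geom)
        d2 = compute_dose_grid(dwells.scaled(2.0), src, geom)
        assert np.allclose(d2.data, 2.0 * d1.data, rtol=1e-12)

    def test_grid_matches_pointwise_brute_force(self):
        dwells = plan_dwells([needle(25.0)])
        src = SourceModel()
        geom = cb.VoxelGrid(np.zeros((6, 6, 6)), 4.0, (-12.0, -12.0, -2.0))
        grid = compute_dose_grid(dwells, src, geom)
        pos = dwells.all_positions
        times = dwells.all_times
        for idx in np.ndindex(geom.shape):
            p = geom.index_to_world(np.array(idx))
            total = 0.0
            for t, q in zip(times, pos):
                r = max(np.sqrt(((p - q) ** 2).sum()), src.min_radius_mm)
                total += t * (10.0 / r) ** 2
            assert grid.data[idx] == pytest.approx(total, abs=1e-12 * max(total, 1.0))


class TestOptimizer:
    def test_single_dwell_closed_form(self):
        ds = single_dwell_set((0.0, 0.0, 0.0))
        src = SourceModel()
        target = np.array([[20.0, 0.0, 0.0]])
        opt = optimize_dwell_times(ds, src, target, prescription=2.0)
        unit = (10.0 / 20.0) ** 2
        assert opt.all_times[0] == pytest.approx(2.0 / unit, rel=1e-9)

    def test_mirror_symmetric_plan_symmetric_times(self):
        trks = cb.generate_implant(ImplantSpec(needle_count=2, ovoid_count=0,
                                               needle_spacing=20.0))
        dwells = plan_dwells([t for t in trks if t.kind == "plastic_needle"])
        src = SourceModel()
        th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        target = np.column_stack([15 * np.cos(th), 7 + 15 * np.sin(th), np.full(16, 40.0)])
        opt = optimize_dwell_times(dwells, src, target, 1.0)
        t0, t1 = opt.channels[0].times, opt.channels[1].times
        assert np.allclose(t0, t1, atol=1e-9)

    def test_three_dwell_toy_against_grid_search(self):
        """Continuous optimum is at least as good as an exhaustive grid."""
        from cbctbrachy.dosimetry import DwellChannel

        ds = DwellSet([DwellChannel("t", "plastic_needle", 5.0,
                                    np.array([5.0, 7.5, 10.0]),
                                    np.array([[0.0, 0, 0], [2.5, 0, 0], [5.0, 0, 0]]),
                                    np.ones(3))])
        src = SourceModel()
        targets = np.array([[10.0, 8.0, 0.0], [-6.0, -9.0, 3.0], [2.0, 12.0, -4.0]])
        prescription = 1.0
        a = np.zeros((3, 3))
        for i, p in enumerate(targets):
            for j, q in enumerate(ds.all_positions):
                r = max(np.linalg.norm(p - q), src.min_radius_mm)
                a[i, j] = (10.0 / r) ** 2
        opt = optimize_dwell_times(ds, src, targets, prescription)
        obj_opt = np.sum((a @ opt.all_times - prescription) ** 2)
        grid = np.arange(0.0, 1.0001, 0.01)
        best = np.inf
        for t0 in grid:
            for t1 in grid:
                resid_partial = a[:, 0] * t0 + a[:, 1] * t1 - prescription
                contrib = a[:, 2]
                # optimal t2 on the grid for this (t0, t1)
                vals = resid_partial[None, :] + contrib[None, :] * grid[:, None]
                best = min(best, float(np.min(np.sum(vals**2, axis=1))))
        assert obj_opt <= best + 1e-4

    def test_oar_hinge_reduces_overdose(self):
        ds = single_dwell_set((0.0, 0.0, 0.0))
        src = SourceModel()
        target = np.array([[15.0, 0.0, 0.0]])
        oar = OARConstraint("oar", np.array([[5.0, 0.0, 0.0]]), limit_dose=1.0,
                            weight=1e6)
        free = optimize_dwell_times(ds, src, target, 1.0)
        constrained = optimize_dwell_times(ds, src, target, 1.0, [oar])
        oar_free = dose_at_point(free, src, (5.0, 0.0, 0.0))
        oar_con = dose_at_point(constrained, src, (5.0, 0.0, 0.0))
        assert oar_free > 1.0
        assert oar_con < oar_free
        assert oar_con == pytest.approx(1.0, rel=1e-2)

    def test_infeasible_plan_flagged(self):
        ds = single_dwell_set((0.0, 0.0, 0.0), time=1.0)
        src = SourceModel(reference_rate=0.0)
        with pytest.warns(UserWarning, match="infeasible"):
            opt = optimize_dwell_times(ds, src, np.array([[20.0, 0.0, 0.0]]), 1.0)
        assert np.all(opt.all_times == 0.0)


class TestDvh:
    def test_uniform_dose_at_prescription(self):
        geom = cb.VoxelGrid(np.full((10, 10, 10), 5.0), 2.0)
        mask = geom.like(np.ones((10, 10, 10)))
        m = dvh_metrics(geom, mask, prescription=5.0)
        assert (m.d90_pct, m.v100_pct, m.d2ccm_pct) == (100.0, 100.0, 100.0)

    def test_brute_force_voxel_sort_agreement(self):
        rng = np.random.default_rng(0)
        doses = rng.uniform(0.0, 3.0, 400)
        vox = 0.008  # 2 mm voxels
        m = dvh_metrics_from_doses(doses, vox, prescription=1.5)
        # oracle: scan thresholds over the sorted doses
        d90 = max(d for d in doses if (doses >= d).sum() * vox >= 0.9 * doses.size * vox)
        v100 = (doses >= 1.5).sum() / doses.size * 100.0
        srt = np.sort(doses)[::-1]
        k = next(i for i in range(doses.size) if (i + 1) * vox >= 2.0)
        assert m.d90_pct == pytest.approx(d90 / 1.5 * 100.0, abs=1e-12)
        assert m.v100_pct == pytest.approx(v100, abs=1e-12)
        assert m.d2ccm_pct == pytest.approx(srt[k] / 1.5 * 100.0, abs=1e-12)

    def test_small_structure_flagged(self):
        with pytest.warns(UserWarning, match="minimum structure dose"):
            m = dvh_metrics_from_doses(np.array([1.0, 2.0, 3.0]), 0.1, 1.0)
        assert m.small_structure
        assert m.d2ccm_pct == pytest.approx(100.0)

    def test_dx_non_increasing_in_x(self):
        from cbctbrachy.dosimetry import dose_percentile

        rng = np.random.default_rng(1)
        doses = rng.uniform(0, 5, 300)
        vols = np.full(300, 0.001)
        levels = [dose_percentile(doses, vols, f) for f in (0.5, 0.7, 0.9, 0.98)]
        assert all(a >= b for a, b in zip(levels, levels[1:]))

    def test_metrics_scale_with_dose(self):
        rng = np.random.default_rng(2)
        doses = rng.uniform(0, 5, 300)
        m1 = dvh_metrics_from_doses(doses, 0.01, 2.0)
        m2 = dvh_metrics_from_doses(3 * doses, 0.01, 3 * 2.0)
        assert m1.d90_pct == pytest.approx(m2.d90_pct)
        assert m1.v100_pct == pytest.approx(m2.v100_pct)
        assert m1.d2ccm_pct == pytest.approx(m2.d2ccm_pct)


class TestEqd2AndTradeoff:
    def test_reference_fractionation_identity(self):
        assert eqd2(40.0, 2.0, 10.0) == pytest.approx(40.0)

    def test_pdr_closed_form(self):
        assert eqd2(45.0, 0.5, 3.0) == pytest.approx(31.5)

    def test_large_alpha_beta_limit(self):
        assert eqd2(45.0, 0.5, 1e6) == pytest.approx(45.0, rel=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            eqd2(-1.0, 2.0, 10.0)

    def test_tradeoff_ratio_forms(self):
        assert tradeoff_ratio(65.0, 65.0) == 1.0
        with pytest.raises(ValueError):
            tradeoff_ratio(10.0, 0.0)

    def test_tradeoff_invariant_to_time_scaling(self):
        tracks = cb.generate_implant(ImplantSpec(needle_count=2, ovoid_count=0))
        dwells = plan_dwells(tracks)
        src = SourceModel()
        pts = np.random.default_rng(3).uniform(-20, 40, (200, 3))
        d1 = dose_at_points(dwells, src, pts)
        d2 = dose_at_points(dwells.scaled(1.7), src, pts)
        m1 = dvh_metrics_from_doses(d1, 0.02, 1.0)
        m2 = dvh_metrics_from_doses(d2, 0.02, 1.0)
        assert tradeoff_ratio(m2.d2ccm_pct, m2.d90_pct) == pytest.approx(
            tradeoff_ratio(m1.d2ccm_pct, m1.d90_pct), rel=1e-9
        )
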