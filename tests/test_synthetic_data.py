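"""Phantom generator, toy dose engine, plan triplets, slab study, cohorts."""

import dataclasses

import numpy as np
import pytest

import gasdose as g
from gasdose.synthetic_data import _beam_dose_along_y


COARSE = g.PhantomSpec(seed=0, spacing=(6.0, 6.0, 6.0))


class TestGeneratePatient:
    def test_same_seed_is_bit_identical(self):
        a = g.generate_patient(g.PhantomSpec(seed=3))
        b = g.generate_patient(g.PhantomSpec(seed=3))
        assert np.array_equal(a.ct.values, b.ct.values)
        for sa, sb in zip(a.structures, b.structures):
            assert sa.name == sb.name
            assert all(za == zb and np.array_equal(va, vb)
                       for (za, va), (zb, vb) in zip(sa.contours, sb.contours))

    def test_expected_structures_present(self):
        case = g.generate_patient(g.PhantomSpec(seed=4))
        for name in ("GTV", "PTV", "ST", "SB", "LB", "GAS"):
            assert name in case.structures

    def test_no_pockets_gives_empty_gas(self):
        case = g.generate_patient(g.PhantomSpec(seed=5, n_pockets=0))
        gas = g.rasterize_structure(case.structures["GAS"], case.ct.grid)
        assert gas.n_voxels == 0

    def test_pocket_hu_recovers_generator_mean(self):
        # fine grid + large pockets so the gas sample is tens of thousands
        # of voxels: the +-3 HU window is then several standard errors wide
        spec = g.PhantomSpec(seed=8, spacing=(2.0, 2.0, 2.0), n_pockets=3,
                             pocket_semiaxes=(20.0, 30.0))
        case = g.generate_patient(spec)
        gas = g.rasterize_structure(case.structures["GAS"], case.ct.grid)
        assert gas.n_voxels > 10_000
        mean = case.ct.values[gas.member].mean()
        assert abs(mean - spec.pocket_hu_mean) < 3.0

    def test_infeasible_pocket_packing_raises(self):
        spec = g.PhantomSpec(seed=1, n_pockets=9, pocket_semiaxes=(25.0, 30.0))
        with pytest.raises(RuntimeError, match="1000 attempts"):
            g.generate_patient(spec)


class TestBeamSet:
    def test_blocked_sectors_are_avoided_and_spacing_is_even(self):
        angles = g.BeamSet().angles_deg()
        assert len(angles) == 24
        for a in angles:
            assert not (110.0 <= a <= 130.0)
            assert not (230.0 <= a <= 250.0)
        gaps = np.diff(angles)
        gaps = gaps[(gaps < 15.0)]  # the two jumps across blocked sectors
        assert np.allclose(gaps, 320.0 / 24)


class TestToyDoseEngine:
    def test_homogeneous_water_depth_dose_monotone_and_symmetric(self):
        n = 41
        red = np.ones((n, n, n))
        fluence = np.ones((n, n))
        dose = _beam_dose_along_y(red, fluence, (2.0, 2.0, 2.0),
                                  g.EngineParams(ere_gain=0.0))
        cax = dose[n // 2, :, n // 2]
        assert np.all(np.diff(cax) < 0)  # monotone beyond (zero) buildup
        assert np.allclose(dose, dose[::-1, :, :])  # lateral symmetry

    def test_doubling_red_halves_isodose_depth(self):
        n = 101
        fluence = np.ones((n, n))
        depths = []
        for scale in (1.0, 2.0):
            dose = _beam_dose_along_y(np.full((n, n, n), scale), fluence,
                                      (2.0, 2.0, 2.0), g.EngineParams(ere_gain=0.0))
            cax = dose[n // 2, :, n // 2]
            depths.append(np.interp(-0.5 * cax[0], -cax, np.arange(n) * 2.0))
        assert depths[0] == pytest.approx(2.0 * depths[1], rel=1e-3)

    def test_engine_is_deterministic(self):
        case = g.generate_patient(COARSE)
        red = g.ScalarVolume(case.ct.grid,
                             np.clip(g.default_calibration().red(
                                 np.clip(case.ct.values, -1000, 0)), 0, None),
                             "RED")
        beams = g.BeamSet(n_beams=4)
        d1 = g.toy_dose_engine(red, beams, g.EngineParams())
        d2 = g.toy_dose_engine(red, beams, g.EngineParams())
        assert np.array_equal(d1.values, d2.values)

    def test_zero_red_raises(self):
        grid = g.VoxelGrid((0, 0, 0), (2, 2, 2), (5, 5, 5))
        red = g.ScalarVolume(grid, np.zeros(grid.shape), "RED")
        with pytest.raises(ValueError, match="zero"):
            g.toy_dose_engine(red, g.BeamSet(), g.EngineParams())


class TestPlanTriplet:
    def test_empty_gas_collapses_to_identical_plans(self):
        case = g.build_plan_triplet(
            g.generate_patient(dataclasses.replace(COARSE, seed=5, n_pockets=0)))
        a, w, gp = (case.doses[p].values for p in ("APLAN", "WPLAN", "GPLAN"))
        assert np.array_equal(a, w) and np.array_equal(w, gp)
        assert g.compare_plans(case, "WPLAN", "APLAN").mean_gpr == 100.0

    def test_differences_localized_to_gas_slab(self, triplet_case):
        gas = g.rasterize_structure(triplet_case.structures["GAS"],
                                    triplet_case.ct.grid)
        zs = triplet_case.ct.grid.axis_coords(2)
        gas_z = zs[gas.member.any(axis=(0, 1))]
        diff = np.abs(triplet_case.doses["WPLAN"].values
                      - triplet_case.doses["APLAN"].values)
        significant = diff > 0.005 * triplet_case.doses["WPLAN"].values.max()
        # beams are coplanar: differences stay within the z-extent of the gas
        # pockets plus the ERE range and penumbra
        far = (zs < gas_z.min() - 16.0) | (zs > gas_z.max() + 16.0)
        assert significant[:, :, far].sum() == 0
        assert significant.sum() > 0

    def test_gpr_ordering_matches_clinical_pattern(self, triplet_case):
        wa = g.compare_plans(triplet_case, "WPLAN", "APLAN").mean_gpr
        wg = g.compare_plans(triplet_case, "WPLAN", "GPLAN").mean_gpr
        ga = g.compare_plans(triplet_case, "GPLAN", "APLAN").mean_gpr
        assert wg > ga > wa

    def test_missing_gas_structure_raises(self):
        case = g.generate_patient(COARSE)
        del case.structures._structures["GAS"]
        with pytest.raises(ValueError, match="GAS"):
            g.build_plan_triplet(case)


@pytest.fixture(scope="module")
def slab():
    return g.slab_experiment([0.0012, 0.1, 0.3, 0.5, 1.0])


class TestSlabExperiment:
    def test_air_self_comparison_is_identity(self, slab):
        table, _ = slab
        assert dict(table)[0.0012] == 100.0

    def test_gpr_decreases_with_largest_drop_at_low_red(self, slab):
        table, _ = slab
        gpr = dict(table)
        assert gpr[0.1] > gpr[0.3] > gpr[1.0]
        assert gpr[0.1] - gpr[0.3] > gpr[0.3] - gpr[1.0]

    def test_pdd_for_half_density_gap_is_nearly_water(self, slab):
        _, pdds = slab
        gap_05 = np.abs(pdds[0.5][1] - pdds[1.0][1]).max()
        gap_01 = np.abs(pdds[0.1][1] - pdds[1.0][1]).max()
        assert gap_05 < 6.0          # percentage points on the PDD
        assert gap_05 < 0.25 * gap_01


class TestSimulateCohort:
    def test_structural_properties_and_csv_round_trip(self, tmp_path):
        records = g.simulate_cohort(5, seed=3, base_spec=COARSE)
        assert len(records) == 5
        for r in records:
            assert set(r.gpr) == set(g.COMPARISONS)
            assert all(0.0 <= v <= 100.0 for v in r.gpr.values())
            assert r.agv_cc >= 0.0
        back = g.read_records_csv(
            g.write_records_csv(records, tmp_path / "c.csv"))
        for orig, rt in zip(records, back):
            assert rt.agv_cc == pytest.approx(orig.agv_cc, rel=1e-12)
            for comp in g.COMPARISONS:
                assert rt.gpr[comp] == pytest.approx(orig.gpr[comp], rel=1e-12)

    def test_all_zero_pocket_cohort_is_degenerate(self):
        spec = dataclasses.replace(COARSE, n_pockets=0)
        records = g.simulate_cohort(5, seed=4, base_spec=spec,
                                    vary_pockets=False)
        assert all(v == 100.0 for r in records for v in r.gpr.values())
        assert all(r.agv_cc == 0.0 for r in records)
        with pytest.raises(ValueError, match="constant"):
            g.pearson_r([r.agv_cc for r in records],
                        [r.gpr["WPLANvsAPLAN"] for r in records])

    def test_agv_monotone_in_pocket_volume_for_fixed_geometry(self):
        small = dataclasses.replace(COARSE, seed=6, n_pockets=3,
                                    pocket_semiaxes=(8.0, 12.0))
        large = dataclasses.replace(COARSE, seed=6, n_pockets=3,
                                    pocket_semiaxes=(20.0, 28.0))
        agvs = []
        for spec in (small, large):
            case = g.build_plan_triplet(g.generate_patient(spec))
            gas = g.rasterize_structure(case.structures["GAS"], case.ct.grid)
            agvs.append(g.compute_agv(gas, case.doses["APLAN"],
                                      case.prescription_dose))
        assert agvs[1] > agvs[0]
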