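"""Gas HU statistics, statistical tests, calibration fit, RED override."""

import numpy as np
import pytest
from scipy import stats

import gasdose as g


def volume_with_mask(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or g.VoxelGrid((0, 0, 0), (1, 1, 1), values.shape)
    return g.ScalarVolume(grid, values, "HU"), grid


class TestStructureHuStats:
    def test_uniform_region(self):
        vol, grid = volume_with_mask(np.full((4, 4, 2), -620.0))
        mask = g.BinaryMask(grid, np.ones(grid.shape, bool))
        mean, sd, n = g.structure_hu_stats(vol, mask)
        assert (mean, sd, n) == (-620.0, 0.0, 32)

    def test_two_voxel_hand_arithmetic(self):
        values = np.zeros((2, 1, 1))
        values[0, 0, 0], values[1, 0, 0] = -600.0, -640.0
        vol, grid = volume_with_mask(values)
        mean, sd, n = g.structure_hu_stats(
            vol, g.BinaryMask(grid, np.ones(grid.shape, bool)))
        assert mean == -620.0
        assert sd == pytest.approx(28.284271, abs=1e-5)

    def test_large_normal_sample_recovers_mean(self):
        rng = np.random.default_rng(77)
        values = np.clip(rng.normal(-620.0, 90.0, (50, 50, 40)), -1000, None)
        vol, grid = volume_with_mask(values)
        mean, sd, n = g.structure_hu_stats(
            vol, g.BinaryMask(grid, np.ones(grid.shape, bool)))
        assert n == 100_000
        assert abs(mean - (-620.0)) < 1.0
        assert abs(sd - 90.0) < 2.0

    def test_empty_mask_raises(self):
        vol, grid = volume_with_mask(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            g.structure_hu_stats(vol, g.BinaryMask(grid, np.zeros(grid.shape, bool)))


class TestKsNormality:
    def test_accepts_normal_samples_at_nominal_rate(self):
        rng = np.random.default_rng(5)
        accepted = sum(g.ks_normality(rng.normal(0, 1, 21)) > 0.05
                       for _ in range(200))
        assert accepted >= 0.95 * 200

    def test_rejects_strong_bimodality(self):
        rng = np.random.default_rng(6)
        rejected = 0
        for _ in range(200):
            signs = rng.choice([-5.0, 5.0], 21)
            rejected += g.ks_normality(signs + rng.normal(0, 0.1, 21)) < 0.05
        assert rejected >= 0.95 * 200

    def test_deterministic_and_guards(self):
        x = [0.1, -0.4, 1.2, 0.5, -1.1]
        assert g.ks_normality(x) == g.ks_normality(x)
        with pytest.raises(ValueError):
            g.ks_normality([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            g.ks_normality([1.0, 2.0])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert g.mann_whitney_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_fully_separated_triples_exact_p(self):
        # U = 0; two-sided exact p = 2 * 1/C(6,3) = 0.1
        assert g.mann_whitney_unpaired([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(9)
        ps = [g.mann_whitney_unpaired(rng.normal(-610, 80, 21),
                                      rng.normal(-610, 80, 21))
              for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            g.mann_whitney_unpaired([], [1.0])


class TestCalibration:
    def test_two_point_line(self):
        curve = g.fit_calibration_segment([(-1000.0, 0.0), (0.0, 1.0)])
        assert curve.slope == pytest.approx(0.001, rel=1e-12)
        assert curve.intercept == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_zero_residual(self):
        pts = [(hu, 1.0 + 0.001 * hu) for hu in (-900, -700, -500, -300, -100)]
        curve = g.fit_calibration_segment(pts)
        resid = sum((r - curve.red(h)) ** 2 for h, r in pts)
        assert resid < 1e-20

    def test_matches_normal_equations_oracle(self, rng):
        hu = rng.uniform(-1000, 0, 30)
        red = 1.0 + 0.001 * hu + rng.normal(0, 0.01, 30)
        red = np.clip(red, 0.0, 1.2)
        curve = g.fit_calibration_segment(list(zip(hu, red)))
        x = np.column_stack([hu, np.ones_like(hu)])
        beta = np.linalg.solve(x.T @ x, x.T @ red)
        assert curve.slope == pytest.approx(beta[0], abs=1e-12)
        assert curve.intercept == pytest.approx(beta[1], abs=1e-12)

    def test_out_of_domain_points_are_ignored(self):
        curve = g.fit_calibration_segment(
            [(-1000.0, 0.0), (0.0, 1.0), (500.0, 99.0), (1500.0, -5.0)])
        assert curve.slope == pytest.approx(0.001, rel=1e-9)
        with pytest.raises(ValueError):
            g.fit_calibration_segment([(-1000.0, 0.0), (200.0, 1.2)])

    def test_giged_endpoints_on_default_curve(self):
        curve = g.default_calibration()
        assert round(g.hu_to_red(curve, -620.0), 2) == 0.38
        assert g.hu_to_red(curve, 0.0) == pytest.approx(1.0, abs=1e-12)
        assert g.hu_to_red(curve, -1000.0) == pytest.approx(0.0, abs=1e-12)

    def test_extrapolation_warns(self):
        curve = g.default_calibration()
        with pytest.warns(UserWarning, match="extrapolat"):
            curve.red(100.0)


class TestOverrideRed:
    def grid_red(self, rng):
        grid = g.VoxelGrid((0, 0, 0), (1, 1, 1), (6, 6, 4))
        red = g.ScalarVolume(grid, rng.uniform(0.0, 1.1, grid.shape), "RED")
        mask = g.BinaryMask(grid, rng.random(grid.shape) < 0.3)
        return red, mask

    def test_identity_and_empty_mask(self, rng):
        red, mask = self.grid_red(rng)
        empty = g.BinaryMask(red.grid, np.zeros(red.grid.shape, bool))
        assert np.array_equal(g.override_red(red, empty, 0.5).values, red.values)

    def test_difference_confined_to_mask_and_no_mutation(self, rng):
        red, mask = self.grid_red(rng)
        before = red.values.copy()
        air = g.override_red(red, mask, 0.0012)
        water = g.override_red(red, mask, 1.0)
        assert np.array_equal(red.values, before)  # input untouched
        differs = air.values != water.values
        assert np.array_equal(differs, mask.member)
        assert np.all(air.values[mask.member] == 0.0012)


class TestGasHuReport:
    def test_pooled_mean_is_voxel_weighted(self):
        stats_in = {"GAS": [(-600.0, 10.0, 100), (-660.0, 10.0, 300)]}
        report = g.gas_hu_report(stats_in)
        assert report.pooled_gas_mean_hu == pytest.approx(-645.0)
        assert report.giged == round(g.hu_to_red(g.default_calibration(), -645.0), 2)

    def test_equal_organ_distributions_reject_at_alpha_rate(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_trials = 300
        for _ in range(n_trials):
            stats_in = {
                "GAS": [(m, 0.0, 100) for m in rng.normal(-620, 90, 21)],
                "STG": [(m, 0.0, 30) for m in rng.normal(-610, 90, 21)],
                "SBG": [(m, 0.0, 30) for m in rng.normal(-610, 90, 21)],
                "LBG": [(m, 0.0, 30) for m in rng.normal(-610, 90, 21)],
            }
            report = g.gas_hu_report(stats_in)
            rejections += sum(p < 0.05 for p in report.pairwise_p.values())
        rate = rejections / (3 * n_trials)
        assert 0.02 <= rate <= 0.08  # ~ alpha = 0.05

    def test_on_synthetic_patient(self):
        case = g.generate_patient(g.PhantomSpec(seed=19, n_pockets=6))
        masks = {"GAS": g.rasterize_structure(case.structures["GAS"], case.ct.grid)}
        gas = masks["GAS"]
        for organ, part in (("ST", "STG"), ("SB", "SBG"), ("LB", "LBG")):
            organ_mask = g.rasterize_structure(case.structures[organ], case.ct.grid)
            masks[part] = g.mask_intersection(gas, organ_mask)
        # the organ partitions are subsets of GAS and together cover it
        union = np.zeros(case.ct.grid.shape, bool)
        for part in ("STG", "SBG", "LBG"):
            assert not np.any(masks[part].member & ~gas.member)
            union |= masks[part].member
        assert union.sum() > 0
        stats_per = {name: [g.structure_hu_stats(case.ct, m)]
                     for name, m in masks.items() if m.n_voxels}
        report = g.gas_hu_report(stats_per)
        assert -700 < report.per_structure["GAS"][0] < -540
        assert 0.0 < report.giged < 1.0
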