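"""Raster operations against hand computations and brute-force oracles."""

import numpy as np
import pytest

from paleofd.grids import ClimateGrid, read_ascii_grid, write_ascii_grid
from paleofd.paleoclimate import (
    DAYS_IN_MONTH,
    RefugiaThresholds,
    accessibility,
    change_factor_downscale,
    climate_velocity,
    coldest_month_mean,
    ensemble_mean,
    growing_degree_days,
    refugia_mask,
    summer_precipitation,
)


def grid(values, cell=50.0, **tags):
    return ClimateGrid(np.asarray(values, dtype=float), cell_size_km=cell, **tags)


class TestAsciiIO:
    def test_round_trip_with_nodata(self, tmp_path):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        vals[1, 2] = np.nan
        g = grid(vals, cell=25.0)
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        back = read_ascii_grid(path)
        np.testing.assert_allclose(back.values, vals)
        assert back.cell_size_km == 25.0

    def test_shape_mismatch_detected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 1\nNODATA_value -9999\n1 2 3\n4 5 6\n")
        with pytest.raises(ValueError):
            read_ascii_grid(path)


class TestEnsembleMean:
    def test_single_grid_identity(self):
        g = grid(np.random.default_rng(0).standard_normal((5, 5)))
        np.testing.assert_array_equal(ensemble_mean([g]).values, g.values)

    def test_two_constants(self):
        out = ensemble_mean([grid(np.ones((4, 4))), grid(3 * np.ones((4, 4)))])
        np.testing.assert_allclose(out.values, 2.0)

    def test_thirteen_members_match_naive_loop(self):
        rng = np.random.default_rng(1)
        members = [grid(rng.standard_normal((6, 7))) for _ in range(13)]
        out = ensemble_mean(members)
        naive = np.zeros((6, 7))
        for i in range(6):
            for j in range(7):
                naive[i, j] = np.mean([m.values[i, j] for m in members])
        np.testing.assert_allclose(out.values, naive, atol=1e-12)

    def test_nodata_ignored_then_propagated(self):
        a = grid([[1.0, np.nan], [np.nan, 4.0]])
        b = grid([[3.0, 2.0], [np.nan, 6.0]])
        out = ensemble_mean([a, b])
        np.testing.assert_allclose(out.values[0], [2.0, 2.0])
        assert np.isnan(out.values[1, 0])
        assert out.values[1, 1] == 5.0

    def test_mismatched_variable_rejected(self):
        a = grid(np.ones((3, 3)), variable="temperature")
        b = grid(np.ones((3, 3)), variable="precipitation")
        with pytest.raises(ValueError):
            ensemble_mean([a, b])


class TestChangeFactorDownscale:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.fine = grid(rng.uniform(0, 10, (10, 10)), cell=10.0)
        self.coarse_p = grid(rng.uniform(0, 10, (5, 5)), cell=20.0)

    def test_constant_temperature_anomaly_exact(self):
        coarse_l = self.coarse_p.with_values(self.coarse_p.values - 10.0)
        out = change_factor_downscale(coarse_l, self.coarse_p, self.fine)
        np.testing.assert_allclose(out.values, self.fine.values - 10.0, atol=1e-10)

    def test_identity_anomaly(self):
        out = change_factor_downscale(self.coarse_p, self.coarse_p, self.fine)
        np.testing.assert_allclose(out.values, self.fine.values, atol=1e-10)

    def test_constant_precipitation_ratio_exact(self):
        fine_p = self.fine.with_values(self.fine.values + 1.0, variable="precipitation")
        coarse_p = self.coarse_p.with_values(
            self.coarse_p.values + 1.0, variable="precipitation"
        )
        coarse_l = coarse_p.with_values(coarse_p.values * 0.5)
        out = change_factor_downscale(coarse_l, coarse_p, fine_p)
        np.testing.assert_allclose(out.values, fine_p.values * 0.5, atol=1e-10)

    def test_mismatched_variables_rejected(self):
        wrong = self.coarse_p.with_values(self.coarse_p.values, variable="precipitation")
        with pytest.raises(ValueError):
            change_factor_downscale(wrong, self.coarse_p, self.fine)


def monthly(values_fn):
    return [
        grid(values_fn(m), variable="temperature", month=m + 1) for m in range(12)
    ]


class TestGrowingDegreeDays:
    def test_at_base_everywhere_zero(self):
        months = monthly(lambda m: np.full((4, 4), 5.0))
        np.testing.assert_allclose(growing_degree_days(months).values, 0.0)

    def test_one_degree_above_base_all_year(self):
        months = monthly(lambda m: np.full((4, 4), 6.0))
        np.testing.assert_allclose(growing_degree_days(months).values, 365.0)

    def test_seasonal_cycle_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        fields = [rng.uniform(-10, 25, (5, 6)) for _ in range(12)]
        months = [grid(f, variable="temperature", month=m + 1) for m, f in enumerate(fields)]
        out = growing_degree_days(months).values
        naive = np.zeros((5, 6))
        for i in range(5):
            for j in range(6):
                naive[i, j] = sum(
                    max(0.0, fields[m][i, j] - 5.0) * DAYS_IN_MONTH[m]
                    for m in range(12)
                )
        np.testing.assert_allclose(out, naive, atol=1e-9)


class TestRefugiaMask:
    def make(self, gdd, tcold, psummer):
        shape = (1, 1)
        return refugia_mask(
            grid(np.full(shape, gdd), variable="gdd"),
            grid(np.full(shape, tcold), variable="tcold"),
            grid(np.full(shape, psummer), variable="psummer"),
        )

    def test_boundary_values_inclusive(self):
        thr = RefugiaThresholds()
        assert self.make(800.0, thr.tcold_min, 50.0).mask[0, 0]

    def test_marginal_gdd_violation_excluded(self):
        thr = RefugiaThresholds()
        assert not self.make(799.9, thr.tcold_min, 50.0).mask[0, 0]

    def test_random_grids_match_triple_condition_oracle(self):
        rng = np.random.default_rng(4)
        gdd = rng.uniform(0, 2000, (8, 8))
        tcold = rng.uniform(-40, 10, (8, 8))
        psum = rng.uniform(0, 120, (8, 8))
        thr = RefugiaThresholds()
        out = refugia_mask(
            grid(gdd, variable="gdd"), grid(tcold, variable="tcold"),
            grid(psum, variable="psummer"), thr,
        )
        oracle = (gdd >= thr.gdd_min) & (tcold >= thr.tcold_min) & (psum >= thr.psummer_min)
        np.testing.assert_array_equal(out.mask, oracle)

    def test_area_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        gdd = grid(rng.uniform(0, 2000, (10, 10)), variable="gdd")
        tcold = grid(rng.uniform(-40, 10, (10, 10)), variable="tcold")
        psum = grid(rng.uniform(0, 120, (10, 10)), variable="psummer")
        areas = [
            refugia_mask(gdd, tcold, psum, RefugiaThresholds(gdd_min=g)).n_refugial
            for g in (400, 800, 1200)
        ]
        assert areas[0] >= areas[1] >= areas[2]


class TestClimateVelocity:
    def test_identical_epochs_zero_velocity(self):
        g = grid(np.random.default_rng(6).uniform(0, 10, (6, 6)))
        v = climate_velocity(g, g)
        np.testing.assert_allclose(v.values, 0.0)

    def test_plane_gradient_hand_example(self):
        """2.1 °C anomaly over a 0.01 °C/km east-west plane → 0.1 km/decade."""
        ncols, cell = 10, 50.0
        xs = (np.arange(ncols) + 0.5) * cell
        present = grid(np.tile(0.01 * xs, (6, 1)), cell=cell)
        lgm = present.with_values(present.values - 2.1, epoch="lgm")
        v = climate_velocity(present, lgm, years=21000.0)
        np.testing.assert_allclose(v.values[1:-1, 1:-1], 0.1, rtol=1e-10)

    def test_flat_grid_floored_and_flagged(self):
        present = grid(np.full((5, 5), 7.0))
        lgm = present.with_values(present.values - 2.0, epoch="lgm")
        v = climate_velocity(present, lgm)
        assert v.gradient_floored.all()
        trend = 2.0 / 2100.0
        np.testing.assert_allclose(v.values, trend / 1e-5)

    def test_invariant_to_common_offset(self):
        rng = np.random.default_rng(7)
        p = grid(rng.uniform(0, 10, (6, 6)))
        l = p.with_values(p.values - rng.uniform(1, 5, (6, 6)), epoch="lgm")
        v1 = climate_velocity(p, l)
        v2 = climate_velocity(
            p.with_values(p.values + 100.0), l.with_values(l.values + 100.0)
        )
        np.testing.assert_allclose(v1.values, v2.values, rtol=1e-10)

    def test_doubling_anomaly_doubles_velocity(self):
        rng = np.random.default_rng(8)
        p = grid(rng.uniform(0, 10, (6, 6)))
        anom = rng.uniform(1, 3, (6, 6))
        v1 = climate_velocity(p, p.with_values(p.values - anom))
        v2 = climate_velocity(p, p.with_values(p.values - 2 * anom))
        np.testing.assert_allclose(v2.values, 2 * v1.values, rtol=1e-10)

    def test_nonpositive_years_rejected(self):
        g = grid(np.ones((4, 4)))
        with pytest.raises(ValueError):
            climate_velocity(g, g, years=0.0)


class TestAccessibility:
    def test_no_refugia_all_zero_with_warning(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        with pytest.warns(UserWarning):
            out = accessibility(coords, np.array([False, False]), cell_size_km=50.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_two_refugia_hand_example(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
        flags = np.array([False, True, True])
        out = accessibility(coords, flags, cell_size_km=50.0)
        assert out[0] == pytest.approx(1 / 100 + 1 / 200, abs=1e-15)

    def test_refugial_cell_gains_self_term(self):
        coords = np.array([[0.0, 0.0], [0.0, 300.0], [150.0, 150.0]])
        base = accessibility(coords, np.array([False, True, False]), cell_size_km=50.0)
        boosted = accessibility(coords, np.array([True, True, False]), cell_size_km=50.0)
        # focal cell 0: self-term 1/(cell/2) added when it is itself refugial
        assert boosted[0] == pytest.approx(base[0] + 1 / 25.0)

    def test_additive_over_disjoint_refugia_sets(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 500, size=(20, 2))
        flags_a = np.zeros(20, bool)
        flags_b = np.zeros(20, bool)
        flags_a[[2, 5]] = True
        flags_b[[11, 17]] = True
        both = flags_a | flags_b
        out = accessibility(coords, both, cell_size_km=50.0)
        parts = accessibility(coords, flags_a, cell_size_km=50.0) + accessibility(
            coords, flags_b, cell_size_km=50.0
        )
        np.testing.assert_allclose(out, parts, rtol=1e-12)

    def test_monotone_in_distance(self):
        near = accessibility(
            np.array([[0.0, 0.0], [100.0, 0.0]]), np.array([False, True]), cell_size_km=50.0
        )[0]
        far = accessibility(
            np.array([[0.0, 0.0], [400.0, 0.0]]), np.array([False, True]), cell_size_km=50.0
        )[0]
        assert near > far
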