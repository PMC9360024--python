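import numpy as np
import pytest
from shapely.geometry import box

from greenexp import (
    Grid,
    LandscapeParams,
    Zone,
    ZoneSet,
    aggregate_fraction,
    exposure_report,
    focal_fraction,
    gen_greenspace,
    gen_population,
    greenspace_coverage,
    population_weighted_exposure,
)
from greenexp.exposure import buffer_sensitivity

from conftest import brute_focal


class TestAggregateFraction:
    def test_all_ones_block(self):
        fine = Grid(values=np.ones((10, 10)), cell_size=10.0)
        coarse = aggregate_fraction(fine, 10)
        assert coarse.shape == (1, 1)
        assert coarse.values[0, 0] == 1.0
        assert coarse.cell_size == 100.0

    def test_block_fraction_37_of_100(self, rng):
        vals = np.zeros(100)
        vals[rng.choice(100, 37, replace=False)] = 1.0
        fine = Grid(values=vals.reshape(10, 10), cell_size=10.0)
        assert aggregate_fraction(fine, 10).values[0, 0] == pytest.approx(0.37)

    def test_non_divisible_dimensions_rejected(self):
        fine = Grid(values=np.zeros((15, 15)), cell_size=10.0)
        with pytest.raises(ValueError, match="divisible"):
            aggregate_fraction(fine, 10)

    def test_non_binary_input_rejected(self):
        fine = Grid(values=np.full((10, 10), 0.5), cell_size=10.0)
        with pytest.raises(ValueError, match="binary"):
            aggregate_fraction(fine, 10)

    def test_nodata_blocks_propagate(self):
        vals = np.ones((4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :2] = True       # whole top-left block missing
        mask[0, 2] = True         # partial block: mean over remaining cells
        vals[0, 2] = 0.0
        fine = Grid(values=vals, cell_size=10.0, nodata_mask=mask)
        coarse = aggregate_fraction(fine, 2)
        assert coarse.nodata_mask[0, 0]
        assert not coarse.nodata_mask[0, 1]
        assert coarse.values[0, 1] == pytest.approx(1.0)  # 0-valued cell is nodata

    def test_coverage_preserved_across_aggregation(self, rng):
        vals = (rng.random((40, 40)) < 0.4).astype(float)
        fine = Grid(values=vals, cell_size=10.0)
        coarse = aggregate_fraction(fine, 10)
        full = np.ones(fine.shape, dtype=bool)
        full_c = np.ones(coarse.shape, dtype=bool)
        assert greenspace_coverage(coarse, full_c) == pytest.approx(
            greenspace_coverage(fine, full), abs=1e-12
        )


class TestFocalFraction:
    def test_constants_are_fixed_points(self):
        for c in (0.0, 0.3, 1.0):
            g = Grid(values=np.full((12, 12), c), cell_size=100.0)
            for radius in (0.0, 100.0, 550.0):
                out = focal_fraction(g, radius)
                np.testing.assert_allclose(out.values, c, atol=1e-12)

    def test_subcell_radius_is_identity(self, small_green):
        out = focal_fraction(small_green, 50.0)
        np.testing.assert_array_equal(out.values, small_green.values)

    def test_five_point_kernel_at_exact_radius(self):
        # center + 4 orthogonal neighbors at exactly 100 m (inclusive) -> 1/5
        vals = np.zeros((5, 5))
        vals[2, 2] = 1.0
        g = Grid(values=vals, cell_size=100.0)
        out = focal_fraction(g, 100.0)
        assert out.values[2, 2] == pytest.approx(0.2)
        assert out.values[2, 1] == pytest.approx(0.2)
        assert out.values[1, 1] == pytest.approx(0.0)  # diagonal at 141 m

    def test_matches_brute_force_oracle(self, rng):
        vals = rng.random((20, 20))
        g = Grid(values=vals, cell_size=100.0)
        for radius in (100.0, 250.0, 420.0):
            out = focal_fraction(g, radius)
            expected = brute_focal(vals, 100.0, radius)
            np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_nodata_cells_excluded_and_renormalized(self):
        vals = np.array([[1.0, 0.0, 0.0]])
        mask = np.array([[False, False, True]])
        g = Grid(values=vals, cell_size=100.0, nodata_mask=mask)
        out = focal_fraction(g, 100.0)
        # cell 1 neighborhood = cells 0 and 1 only (cell 2 nodata)
        assert out.values[0, 1] == pytest.approx(0.5)
        assert out.nodata_mask[0, 2]


class TestZonalStats:
    def test_coverage_mean(self):
        g = Grid(values=np.array([[0.0, 0.5], [0.5, 1.0]]), cell_size=100.0)
        assert greenspace_coverage(g, np.ones((2, 2), bool)) == pytest.approx(0.5)

    def test_coverage_extremes(self):
        ones = Grid(values=np.ones((3, 3)), cell_size=10.0)
        zeros = Grid(values=np.zeros((3, 3)), cell_size=10.0)
        m = np.ones((3, 3), bool)
        assert greenspace_coverage(ones, m) == 1.0
        assert greenspace_coverage(zeros, m) == 0.0

    def test_empty_zone_rejected(self):
        g = Grid(values=np.ones((3, 3)), cell_size=10.0)
        with pytest.raises(ValueError, match="empty zone"):
            greenspace_coverage(g, np.zeros((3, 3), bool))

    def test_exposure_hand_example(self):
        pop = Grid(values=np.array([[1.0, 3.0]]), cell_size=100.0)
        gd = Grid(values=np.array([[0.2, 0.6]]), cell_size=100.0)
        ge = population_weighted_exposure(pop, gd, np.ones((1, 2), bool))
        assert ge == pytest.approx(0.5)

    def test_uniform_population_reduces_to_plain_mean(self, rng):
        vals = rng.random((10, 10))
        gd = Grid(values=vals, cell_size=100.0)
        pop = Grid(values=np.full((10, 10), 7.0), cell_size=100.0)
        ge = population_weighted_exposure(pop, gd, np.ones((10, 10), bool))
        assert ge == pytest.approx(vals.mean(), abs=1e-12)

    def test_point_population_selects_single_cell(self, rng):
        vals = rng.random((6, 6))
        gd = Grid(values=vals, cell_size=100.0)
        pop_vals = np.zeros((6, 6))
        pop_vals[4, 2] = 99.0
        pop = Grid(values=pop_vals, cell_size=100.0)
        ge = population_weighted_exposure(pop, gd, np.ones((6, 6), bool))
        assert ge == pytest.approx(vals[4, 2])

    def test_zero_population_zone_rejected(self):
        gd = Grid(values=np.ones((2, 2)), cell_size=100.0)
        pop = Grid(values=np.zeros((2, 2)), cell_size=100.0)
        with pytest.raises(ValueError, match="no population"):
            population_weighted_exposure(pop, gd, np.ones((2, 2), bool))


class TestExposureReport:
    def _landscape(self, rho, seed=21):
        lp = LandscapeParams(shape=(48, 48), pop_clustering=1.5,
                             pop_green_corr=rho, seed=seed)
        g = gen_greenspace(lp)
        return g, gen_population(lp, g)

    def test_composition_matches_direct_ops(self):
        g, p = self._landscape(0.0)
        zones = ZoneSet([Zone("z", box(0, -4800, 4800, 0))])
        res = exposure_report(g, p, zones, [500.0])[0]
        assert res.error is None
        full = np.ones(g.shape, bool)
        assert res.GC == pytest.approx(greenspace_coverage(g, full))
        gd = focal_fraction(g, 500.0)
        assert res.GE_by_radius[500.0] == pytest.approx(
            population_weighted_exposure(p, gd, full)
        )
        assert res.cell_pairs.shape == (48 * 48, 2)

    def test_antirrelated_population_underexposes(self):
        g, p = self._landscape(-0.8)
        zones = ZoneSet([Zone("z", box(0, -4800, 4800, 0))])
        res = exposure_report(g, p, zones, [500.0])[0]
        assert res.GE_by_radius[500.0] < res.GC

    def test_all_radii_reported_in_unit_interval(self):
        g, p = self._landscape(0.3)
        zones = ZoneSet([Zone("z", box(0, -4800, 4800, 0))])
        res = exposure_report(g, p, zones, [100.0, 500.0, 1000.0, 1500.0])[0]
        assert len(res.GE_by_radius) == 4
        assert all(0.0 <= v <= 1.0 for v in res.GE_by_radius.values())

    def test_weighted_mean_bounds(self):
        g, p = self._landscape(-0.5, seed=22)
        zones = ZoneSet([
            Zone("a", box(0, -4800, 2400, 0)),
            Zone("b", box(2400, -4800, 4800, 0)),
        ])
        from greenexp.grid_io import rasterize_zones

        labels = rasterize_zones(zones, g)
        gd = focal_fraction(g, 500.0)
        for k, res in enumerate(exposure_report(g, p, zones, [500.0]), start=1):
            in_zone = gd.values[labels == k]
            ge = res.GE_by_radius[500.0]
            assert in_zone.min() - 1e-12 <= ge <= in_zone.max() + 1e-12

    def test_failing_zone_flagged_not_dropped(self):
        g = Grid(values=np.ones((4, 4)) * 0.5, cell_size=100.0)
        p = Grid(values=np.zeros((4, 4)), cell_size=100.0)
        zones = ZoneSet([
            Zone("inside", box(0, -400, 400, 0)),
            Zone("outside", box(9000, 9000, 9500, 9500)),
        ])
        results = exposure_report(g, p, zones, [500.0])
        assert [r.zone_id for r in results] == ["inside", "outside"]
        assert "no population" in results[0].error
        assert "empty zone" in results[1].error


class TestBufferSensitivity:
    def _result(self, zone_id, ge_by_radius):
        from greenexp.exposure import ExposureResult

        return ExposureResult(zone_id=zone_id, GE_by_radius=ge_by_radius)

    def test_identical_radii_give_zero(self):
        res = [self._result("a", {500.0: 0.4, 1500.0: 0.5})]
        assert buffer_sensitivity(res, 500.0, 500.0) == 0.0

    def test_mean_absolute_discrepancy_in_percentage_points(self):
        res = [
            self._result("a", {500.0: 0.40, 1500.0: 0.41}),
            self._result("b", {500.0: 0.40, 1500.0: 0.43}),
        ]
        assert buffer_sensitivity(res, 500.0, 1500.0) == pytest.approx(2.0)

    def test_constant_grid_insensitive_to_radius(self):
        g = Grid(values=np.full((20, 20), 0.6), cell_size=100.0)
        p = Grid(values=np.ones((20, 20)), cell_size=100.0)
        zones = ZoneSet([Zone("z", box(0, -2000, 2000, 0))])
        res = exposure_report(g, p, zones, [500.0, 1500.0])
        assert buffer_sensitivity(res, 500.0, 1500.0) == pytest.approx(0.0, abs=1e-10)

    def test_missing_radius_rejected(self):
        res = [self._result("a", {500.0: 0.4})]
        with pytest.raises(ValueError, match="not both present"):
            buffer_sensitivity(res, 500.0, 1500.0)
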