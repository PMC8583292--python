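"""Density grids, five-class scoring, layer summation, Gi* and Jenks breaks."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from ecodegrade.density import (assign_breaks_classes, classify_density,
                                confidence_bins, gi_star, natural_breaks,
                                rasterize_density, sum_layers)
from ecodegrade.errors import AlignmentError, ClassingError, SimulationSpecError
from ecodegrade.features import DEGRADED, NATURAL, EcosystemFeature
from ecodegrade.grid import Grid, make_grid

from conftest import square
from oracles import gi_star_brute, jenks_exhaustive


def grid4(cell=1000.0):
    return make_grid((0, 0, 4 * cell, 4 * cell), cell)


class TestRasterizeDensity:
    def test_single_degraded_point_count_mode(self):
        g = grid4()
        f = EcosystemFeature("p", "cave", Point(500, 500), degradation_class=DEGRADED)
        d = rasterize_density([f], g, "count")
        assert d.values[3, 0] == pytest.approx(1 / g.cell_area_km2)
        assert d.values.sum() == pytest.approx(1 / g.cell_area_km2)

    def test_line_split_equally_between_two_cells(self):
        g = grid4()
        line = EcosystemFeature("r", "river", LineString([(500, 500), (1500, 500)]),
                                degradation_class=DEGRADED)
        d = rasterize_density([line], g, "length")
        expected = 0.5 / g.cell_area_km2  # 0.5 km in each cell
        assert d.values[3, 0] == pytest.approx(expected)
        assert d.values[3, 1] == pytest.approx(expected)
        assert d.values.sum() == pytest.approx(2 * expected)

    def test_polygon_area_mode_exact(self):
        g = grid4()
        f = square(1000, 1000, side=2000, degradation_class=DEGRADED)
        d = rasterize_density([f], g, "area")
        # 2x2 km square centered on a grid node: 1 km^2 in each of 4 cells
        assert d.values[2, 0] == pytest.approx(1.0)
        assert d.values.sum() == pytest.approx(4.0)

    def test_non_degraded_features_excluded(self):
        g = grid4()
        f = square(500, 500, degradation_class=NATURAL)
        assert rasterize_density([f], g, "area").values.sum() == 0

    def test_unknown_mode(self):
        with pytest.raises(SimulationSpecError):
            rasterize_density([], grid4(), "volume")


class TestClassifyDensity:
    def test_five_distinct_values_score_1_to_5(self):
        g = Grid(0, 0, 1000, np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        s = classify_density(g, k=5)
        assert list(s.values[0]) == [1, 2, 3, 4, 5]

    def test_all_equal_positive_scores_low(self):
        g = Grid(0, 0, 1000, np.full((3, 3), 2.5))
        assert (classify_density(g, k=5).values == 1).all()

    def test_single_positive_value_equal_interval_collapses_low(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 4.2
        s = classify_density(Grid(0, 0, 1000, vals), k=5, method="equal-interval")
        assert s.values[1, 1] == 1
        assert s.values.sum() == 1

    def test_zero_cells_score_zero(self):
        vals = np.array([[0.0, 1.0], [2.0, 0.0]])
        s = classify_density(Grid(0, 0, 1000, vals), k=2)
        assert s.values[0, 0] == 0 and s.values[1, 1] == 0
        assert s.values[0, 1] >= 1 and s.values[1, 0] >= 1

    def test_all_zero_grid_warns(self, caplog):
        s = classify_density(Grid(0, 0, 1000, np.zeros((2, 2))), k=5)
        assert (s.values == 0).all()

    def test_scores_weakly_increase_with_density(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2.0, 1.0, size=(8, 8))
        for method in ("quantile", "equal-interval"):
            s = classify_density(Grid(0, 0, 1000, vals), k=5, method=method)
            order = np.argsort(vals.ravel())
            assert (np.diff(s.values.ravel()[order]) >= 0).all()


class TestSumLayers:
    def test_all_zero_and_all_five(self):
        zeros = [Grid(0, 0, 1000, np.zeros((3, 3))) for _ in range(6)]
        assert (sum_layers(zeros).values == 0).all()
        fives = [Grid(0, 0, 1000, np.full((3, 3), 5.0)) for _ in range(6)]
        assert (sum_layers(fives).values == 30).all()

    def test_matches_cell_loop_oracle_and_commutes(self):
        rng = np.random.default_rng(11)
        grids = [Grid(0, 0, 500, rng.integers(0, 6, size=(6, 5)).astype(float))
                 for _ in range(4)]
        total = sum_layers(grids)
        for r in range(6):
            for c in range(5):
                assert total.values[r, c] == sum(g.values[r, c] for g in grids)
        total_rev = sum_layers(grids[::-1])
        assert np.array_equal(total.values, total_rev.values)

    def test_misaligned_grids_rejected(self):
        a = Grid(0, 0, 1000, np.zeros((3, 3)))
        b = Grid(500, 0, 1000, np.zeros((3, 3)))
        with pytest.raises(AlignmentError):
            sum_layers([a, b])


class TestGiStar:
    def test_constant_field_all_zero(self):
        g = Grid(0, 0, 1000, np.full((5, 5), 3.0))
        assert (gi_star(g, 1000).z.values == 0).all()

    def test_single_hot_center_matches_brute_force(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 10.0
        g = Grid(0, 0, 1000, vals)
        z = gi_star(g, 1000).z.values
        expected = gi_star_brute(vals, 1000, 1000)
        np.testing.assert_allclose(z, expected, atol=1e-10)
        assert z[2, 2] > 0  # the spike is locally hot

    @pytest.mark.parametrize("seed,radius", [(0, 1000), (1, 1500), (2, 2500)])
    def test_random_grids_match_brute_force(self, seed, radius):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(2.0, 1.0, size=(10, 10))
        g = Grid(0, 0, 1000, vals)
        np.testing.assert_allclose(gi_star(g, radius).z.values,
                                   gi_star_brute(vals, 1000, radius), atol=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 2, size=(8, 8))
        g1 = Grid(0, 0, 1000, vals)
        g2 = Grid(0, 0, 1000, vals + 17.3)
        np.testing.assert_allclose(gi_star(g1, 2000).z.values,
                                   gi_star(g2, 2000).z.values, atol=1e-9)

    def test_geometric_symmetry(self):
        """Mirroring the field mirrors the z surface (weights depend only on
        distance)."""
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(7, 9))
        z = gi_star(Grid(0, 0, 1000, vals), 2000).z.values
        z_flip = gi_star(Grid(0, 0, 1000, vals[::-1]), 2000).z.values
        np.testing.assert_allclose(z[::-1], z_flip, atol=1e-12)

    def test_too_small_inputs_rejected(self):
        with pytest.raises(SimulationSpecError):
            gi_star(Grid(0, 0, 1000, np.ones((1, 1))), 1000)
        with pytest.raises(SimulationSpecError):
            gi_star(Grid(0, 0, 1000, np.ones((3, 3))), 500)

    def test_null_calibration_significance_fraction(self):
        """On iid fields the fraction of |z| > 1.96 sits near the nominal 5%
        (Gi* z-scores are approximately standard normal under the null)."""
        rng = np.random.default_rng(42)
        exceed = total = 0
        for _ in range(200):
            vals = rng.permutation(rng.normal(5, 1, size=400)).reshape(20, 20)
            z = gi_star(Grid(0, 0, 1000, vals), 2000).z.values
            exceed += (np.abs(z) > 1.96).sum()
            total += z.size
        assert 0.03 <= exceed / total <= 0.08


class TestConfidenceBins:
    @pytest.mark.parametrize("z,code", [
        (3.0, 3), (2.0, 2), (1.7, 1), (0.0, 0), (1.0, 0),
        (-2.0, -2), (-3.0, -3), (-1.7, -1),
    ])
    def test_bin_codes(self, z, code):
        g = Grid(0, 0, 1000, np.array([[z, 0.0]]))
        assert confidence_bins(g).values[0, 0] == code

    def test_non_finite_becomes_not_significant(self, caplog):
        g = Grid(0, 0, 1000, np.array([[np.nan, 3.0]]))
        bins = confidence_bins(g).values
        assert bins[0, 0] == 0 and bins[0, 1] == 3


class TestNaturalBreaks:
    def test_perfectly_separated(self):
        (b,) = natural_breaks([1, 1, 1, 10, 10, 10], 2)
        assert 1 <= b < 10

    def test_matches_exhaustive_optimum(self):
        vals = [1, 2, 3, 10, 11, 20, 21, 22]
        breaks = natural_breaks(vals, 3)
        oracle_breaks, _ = jenks_exhaustive(vals, 3)
        assert breaks == oracle_breaks

    @pytest.mark.parametrize("seed,n,k", [(0, 8, 2), (1, 10, 3), (2, 12, 4), (3, 9, 5)])
    def test_random_inputs_match_exhaustive_ssd(self, seed, n, k):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(0, 100, size=n), 2).tolist()
        breaks = natural_breaks(vals, k)
        _, best_ssd = jenks_exhaustive(vals, k)
        # recompute SSD of the returned partition
        classes = assign_breaks_classes(vals, breaks)
        got = sum(
            float(np.sum((np.array([v for v, c in zip(vals, classes) if c == ci])
                          - np.mean([v for v, c in zip(vals, classes) if c == ci])) ** 2))
            for ci in set(classes)
        )
        assert got == pytest.approx(best_ssd, abs=1e-8)

    def test_k_equals_n_distinct(self):
        vals = [4.0, 1.0, 3.0, 2.0]
        assert natural_breaks(vals, 4) == [1.0, 2.0, 3.0]

    def test_too_few_distinct_values(self):
        with pytest.raises(ClassingError):
            natural_breaks([1, 1, 2, 2], 3)
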