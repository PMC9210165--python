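"""Quadrat grid, topographic attributes and rock/soil classification."""

import math
from itertools import combinations

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from karststand.config import StandConfig
from karststand.synthetic import generate_substrate
from karststand.terrain import (
    GeometryError,
    SubstrateMap,
    build_quadrat_grid,
    classify_site_type,
    quadrat_aspect,
    quadrat_convexity,
    quadrat_elevation,
    quadrat_slope,
    rock_fraction,
)


class TestGrid:
    def test_plot_yields_220_quadrats(self):
        grid = build_quadrat_grid(200, 110, 10)
        assert len(grid) == 220
        assert grid.nrows == 11 and grid.ncols == 20

    def test_single_cell_plot(self):
        grid = build_quadrat_grid(10, 10, 10)
        assert len(grid) == 1
        assert grid.cells[0].polygon().equals(box(0, 0, 10, 10))

    def test_non_divisible_dims_error_names_remainder(self):
        with pytest.raises(GeometryError, match="remainder"):
            build_quadrat_grid(205, 110, 10)

    def test_membership_matches_exhaustive_oracle(self):
        """Half-open cell membership on a 0.5 m lattice agrees with a
        brute-force rectangle scan; boundary points go to the last cell."""
        grid = build_quadrat_grid(30, 20, 10)
        assert len(grid) == 6
        xs = np.arange(0.0, 30.0001, 0.5)
        ys = np.arange(0.0, 20.0001, 0.5)
        for x in xs:
            for y in ys:
                row, col = grid.cell_index_of(x, y)
                matches = [
                    (q.row, q.col)
                    for q in grid
                    if (q.x0 <= x < q.x1 or (x == 30 and q.x1 == 30 and q.x0 <= x))
                    and (q.y0 <= y < q.y1 or (y == 20 and q.y1 == 20 and q.y0 <= y))
                ]
                assert matches == [(int(row), int(col))]

    def test_cells_tile_plot(self):
        grid = build_quadrat_grid(200, 110, 10)
        total = sum(q.area for q in grid)
        assert total == pytest.approx(200 * 110, rel=1e-9)


class TestElevationAttributes:
    def test_mean_of_vertices(self):
        assert quadrat_elevation([0, 0, 0, 0]) == 0.0
        assert quadrat_elevation([10, 20, 30, 40]) == 25.0

    def test_missing_vertex_errors(self):
        with pytest.raises(GeometryError):
            quadrat_elevation([1.0, 2.0, math.nan, 3.0])

    def test_convexity_center_above(self):
        assert quadrat_convexity(5.0, [0, 0, 0, 0]) == 5.0

    def test_convexity_planar_is_zero(self):
        # centre = bilinear interpolant of corners on any plane
        z = lambda x, y: 3.0 + 0.2 * x - 0.1 * y
        verts = [z(0, 0), z(10, 0), z(10, 10), z(0, 10)]
        assert quadrat_convexity(z(5, 5), verts) == pytest.approx(0.0, abs=1e-9)

    def test_convexity_mound(self):
        z = lambda x, y: 1.0 + 0.1 * x
        verts = [z(0, 0), z(10, 0), z(10, 10), z(0, 10)]
        assert quadrat_convexity(z(5, 5) + 2.0, verts) == pytest.approx(2.0)


def _plane_oracle(p1, p2, p3):
    """Independent cross-product oracle: dip angle and downslope azimuth."""
    v1 = np.subtract(p2, p1)
    v2 = np.subtract(p3, p1)
    n = np.cross(v1, v2)
    if n[2] < 0:
        n = -n
    dip = math.degrees(math.acos(abs(n[2]) / np.linalg.norm(n)))
    az = math.degrees(math.atan2(n[0] / n[2], n[1] / n[2])) % 360 if dip > 0 else math.nan
    return dip, az


class TestSlopeAspect:
    def test_flat_quadrat_slope_zero(self):
        verts = [(0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 0)]
        assert quadrat_slope(verts) == pytest.approx(0.0)

    def test_coplanar_45_degrees(self):
        verts = [(0, 0, 0), (10, 0, 0), (10, 10, 10), (0, 10, 10)]
        assert quadrat_slope(verts) == pytest.approx(45.0)

    def test_mixed_triples_against_oracle(self):
        """One raised corner: the four triple planes dip 0, 45, 54.7356 and
        45 degrees; the quadrat slope is their mean, 36.1839."""
        verts = [(0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 10)]
        dips = [_plane_oracle(*[verts[i] for i in tri]) [0]
                for tri in combinations(range(4), 3)]
        assert sorted(round(d, 4) for d in dips) == [0.0, 45.0, 45.0, 54.7356]
        assert quadrat_slope(verts) == pytest.approx(np.mean(dips))
        assert quadrat_slope(verts) == pytest.approx(36.1839, abs=1e-4)

    def test_degenerate_triple_errors(self):
        verts = [(0, 0, 0), (5, 5, 0), (10, 10, 0), (2, 2, 1)]
        with pytest.raises(GeometryError, match="collinear"):
            quadrat_slope(verts)

    def test_aspect_due_south(self):
        # plane z = y: elevation rises northward, so descent is due south
        verts = [(0, 0, 0), (10, 0, 0), (10, 10, 10), (0, 10, 10)]
        assert quadrat_aspect(verts) == pytest.approx(180.0)

    def test_aspect_due_north(self):
        verts = [(0, 0, 10), (10, 0, 10), (10, 10, 0), (0, 10, 0)]
        assert quadrat_aspect(verts) == pytest.approx(0.0, abs=1e-9)

    def test_aspect_circular_mean_across_north_wrap(self):
        """Triple aspects straddling north (e.g. 350 and 10 degrees) must
        average to 0, not 180."""
        from karststand.terrain import _plane_aspect

        n350 = np.array([math.sin(math.radians(350)), math.cos(math.radians(350)), 1.0])
        n10 = np.array([math.sin(math.radians(10)), math.cos(math.radians(10)), 1.0])
        assert _plane_aspect(n350) == pytest.approx(350.0)
        assert _plane_aspect(n10) == pytest.approx(10.0)
        ang = np.radians([350.0, 10.0])
        circ = math.degrees(
            math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        ) % 360
        # circular distance to north, not raw difference (0 == 360)
        assert min(circ, 360.0 - circ) == pytest.approx(0.0, abs=1e-9)

    def test_twisted_quadrat_aspect_matches_oracle(self):
        """Non-coplanar vertices: aspect equals the circular mean of the
        per-triple downslope azimuths from the cross-product oracle."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            z = rng.normal(0, 3, size=4)
            verts = [(0, 0, z[0]), (10, 0, z[1]), (10, 10, z[2]), (0, 10, z[3])]
            azs = []
            for tri in combinations(range(4), 3):
                dip, az = _plane_oracle(*[verts[i] for i in tri])
                if dip > 1e-9:
                    azs.append(az)
            ang = np.radians(azs)
            expected = math.degrees(
                math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
            ) % 360
            assert quadrat_aspect(verts) == pytest.approx(expected, abs=1e-9)


class TestSubstrateClassification:
    def _grid1(self):
        return build_quadrat_grid(10, 10, 10)

    def test_full_cover(self):
        grid = self._grid1()
        sub = SubstrateMap([box(-1, -1, 11, 11)], 10, 10)
        assert rock_fraction(grid.cells[0], sub) == pytest.approx(1.0)

    def test_no_overlap(self):
        grid = build_quadrat_grid(20, 10, 10)
        sub = SubstrateMap([box(0, 0, 10, 10)], 20, 10)
        assert rock_fraction(grid.cell(0, 1), sub) == pytest.approx(0.0)

    def test_half_cell_is_rock_boundary_of_rule(self):
        grid = self._grid1()
        sub = SubstrateMap([box(0, 0, 10, 5)], 10, 10)
        assert rock_fraction(grid.cells[0], sub) == pytest.approx(0.5)
        totals = classify_site_type(grid, sub)
        assert grid.cells[0].site_type == "rock"
        assert totals["n_rock_quadrats"] == 1

    def test_threshold_semantics(self):
        grid = build_quadrat_grid(30, 10, 10)
        sub = SubstrateMap(
            [box(0, 0, 4.9, 10), box(10, 0, 15, 10), box(20, 0, 25.1, 10)], 30, 10
        )
        classify_site_type(grid, sub)
        assert [q.site_type for q in grid] == ["soil", "rock", "rock"]

    def test_invalid_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(GeometryError, match="feature 0"):
            SubstrateMap([bowtie], 10, 10)

    def test_all_soil(self):
        grid = build_quadrat_grid(200, 110, 10)
        totals = classify_site_type(grid, SubstrateMap([], 200, 110))
        assert totals["n_rock_quadrats"] == 0
        assert totals["soil_quadrat_area"] == pytest.approx(22000.0)

    def test_partition_and_area_conservation(self, small_grid, small_scenario):
        sub = small_scenario.substrate
        assert all(q.site_type in ("rock", "soil") for q in small_grid)
        assert sub.total_rock_area + sub.total_soil_area == pytest.approx(
            sub.plot_area, rel=1e-9
        )
        # clipping conservation: per-cell intersections sum to the union area
        cell_sum = sum(q.rock_fraction * q.area for q in small_grid)
        assert cell_sum == pytest.approx(sub.total_rock_area, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_rock_fractions_match_raster_oracle(self, seed):
        """Exact polygon clipping agrees with a 0.1 m rasterization within
        0.01 for every quadrat of random substrate scenarios."""
        cfg = StandConfig(
            plot_width=60,
            plot_height=40,
            n_stems=5,
            rock_target_fraction=0.3,
            rock_blob_params=(6, 8.0),
            seed=seed,
        )
        sub = generate_substrate(cfg)
        grid = build_quadrat_grid(60, 40, 10)
        classify_site_type(grid, sub)
        off = np.arange(0.05, 10.0, 0.1)
        for q in grid:
            gx, gy = np.meshgrid(q.x0 + off, q.y0 + off)
            raster = shapely.contains_xy(sub.union, gx.ravel(), gy.ravel()).mean()
            assert abs(raster - q.rock_fraction) < 0.01
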