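"""Gridding, point assignment and polygon-overlay geometry."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from agromapa.geo_core import (
    Grid,
    LandraceRecord,
    Territory,
    assign_records,
    build_grid,
    coverage_percent,
    coverage_percent_table,
    union_layer,
)

KM = 1000.0


class TestBuildGrid:
    @pytest.mark.parametrize(
        "side_km,expected_cells",
        [(40, 4), (50, 9), (20, 1), (60, 9)],
        ids=["exact-2x2", "partial-3x3", "single", "exact-3x3"],
    )
    def test_cell_count_on_aligned_squares(self, side_km, expected_cells):
        territory = Territory(boundary=box(0, 0, side_km * KM, side_km * KM))
        grid = build_grid(territory, 20 * KM)
        assert len(grid) == expected_cells

    def test_partial_cells_are_full_squares(self):
        territory = Territory(boundary=box(0, 0, 50 * KM, 50 * KM))
        grid = build_grid(territory, 20 * KM)
        for q in grid:
            assert q.geometry.area == pytest.approx((20 * KM) ** 2)
            assert q.cell_area == (20 * KM) ** 2

    def test_origin_snaps_to_cell_multiple(self):
        territory = Territory(boundary=box(13 * KM, 27 * KM, 53 * KM, 67 * KM))
        grid = build_grid(territory, 20 * KM)
        assert grid.origin == (0.0, 20 * KM)

    def test_hole_not_removing_full_cell_keeps_count(self):
        outer = box(0, 0, 60 * KM, 60 * KM)
        holed = Polygon(outer.exterior.coords, [box(25 * KM, 25 * KM, 35 * KM, 35 * KM).exterior.coords])
        n_holed = len(build_grid(Territory(boundary=holed), 20 * KM))
        n_full = len(build_grid(Territory(boundary=outer), 20 * KM))
        assert n_holed == n_full == 9

    def test_hole_swallowing_a_cell_drops_it(self):
        outer = box(0, 0, 60 * KM, 60 * KM)
        holed = Polygon(
            outer.exterior.coords, [box(20 * KM, 20 * KM, 40 * KM, 40 * KM).exterior.coords]
        )
        grid = build_grid(Territory(boundary=holed), 20 * KM)
        assert len(grid) == 8
        assert grid.get(1, 1) is None

    def test_touching_cell_with_zero_area_excluded(self):
        # territory exactly fills one cell; neighbours only touch its edges
        territory = Territory(boundary=box(0, 0, 20 * KM, 20 * KM))
        assert len(build_grid(territory, 20 * KM)) == 1

    def test_cells_tile_without_overlap_and_cover_territory(self):
        territory = Territory(
            boundary=box(5 * KM, 5 * KM, 47 * KM, 33 * KM)
        )
        grid = build_grid(territory, 20 * KM)
        cells = [q.geometry for q in grid]
        union = union_layer([cells])
        assert union.area == pytest.approx(sum(c.area for c in cells))  # disjoint
        assert union.covers(territory.boundary)

    def test_empty_territory_rejected(self):
        with pytest.raises(ValueError, match="empty territory"):
            Territory(boundary=Polygon())

    def test_geographic_crs_rejected(self):
        with pytest.raises(ValueError, match="projected/metric"):
            Territory(boundary=box(0, 0, 1, 1), crs_id="EPSG:4326")

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(ValueError):
            build_grid(Territory(boundary=box(0, 0, KM, KM)), 0.0)


class TestAssignRecords:
    def _grid(self, side_km=100):
        return build_grid(Territory(boundary=box(0, 0, side_km * KM, side_km * KM)), 20 * KM)

    def test_point_on_shared_edge_goes_right(self):
        grid = self._grid(40)
        rec = LandraceRecord("r1", "lr", "sp", 20 * KM, 10 * KM)
        assignment, unassigned = assign_records([rec], grid)
        assert not unassigned
        assert assignment["q0_1"] == [rec]
        assert assignment["q0_0"] == []

    def test_all_points_in_one_cell(self):
        grid = self._grid(40)
        recs = [
            LandraceRecord(f"r{i}", f"lr{i}", "sp", (5 + i * 0.1) * KM, 5 * KM)
            for i in range(7)
        ]
        assignment, unassigned = assign_records(recs, grid)
        assert len(assignment["q0_0"]) == 7
        assert not unassigned
        assert all(not v for k, v in assignment.items() if k != "q0_0")

    def test_out_of_grid_points_bucketed_not_erroring(self):
        grid = self._grid(40)
        rec = LandraceRecord("r1", "lr", "sp", -5 * KM, 5 * KM)
        assignment, unassigned = assign_records([rec], grid)
        assert unassigned == [rec]
        assert sum(len(v) for v in assignment.values()) == 0

    def test_matches_geometric_oracle_on_random_points(self):
        """Arithmetic assignment must agree with a brute-force point-in-cell
        check (half-open edges adjudicated to the right/upper cell)."""
        rng = np.random.default_rng(42)
        grid = self._grid(100)  # 5x5
        xy = rng.uniform(0, 100 * KM, size=(1000, 2))
        # snap some points onto cell edges to exercise the tie rule
        xy[:50, 0] = rng.integers(1, 5, size=50) * 20 * KM
        recs = [
            LandraceRecord(f"r{i}", f"lr{i}", "sp", float(x), float(y))
            for i, (x, y) in enumerate(xy)
        ]
        assignment, unassigned = assign_records(recs, grid)
        assert not unassigned

        by_record = {r.record_id: qid for qid, rs in assignment.items() for r in rs}
        for rec in recs:
            homes = [
                q.id
                for q in grid
                if q.geometry.intersects(Point(rec.x, rec.y))
            ]
            # the half-open rule picks the cell whose lower-left corner is
            # closest below/left of the point
            expected = None
            for qid in homes:
                q = next(qq for qq in grid if qq.id == qid)
                minx, miny, maxx, maxy = q.geometry.bounds
                if minx <= rec.x < maxx and miny <= rec.y < maxy:
                    expected = qid
            assert by_record[rec.record_id] == expected

    def test_partition_sizes_sum(self):
        rng = np.random.default_rng(0)
        grid = self._grid(60)
        recs = [
            LandraceRecord(f"r{i}", f"lr{i}", "sp", float(x), float(y))
            for i, (x, y) in enumerate(rng.uniform(-10 * KM, 70 * KM, size=(500, 2)))
        ]
        assignment, unassigned = assign_records(recs, grid)
        assert sum(len(v) for v in assignment.values()) == len(recs) - len(unassigned)


class TestUnionLayer:
    def test_idempotent_on_identical_squares(self):
        sq = box(0, 0, math.sqrt(10) * KM, math.sqrt(10) * KM)
        assert union_layer([[sq], [sq]]).area == pytest.approx(sq.area)

    def test_disjoint_squares_add(self):
        a, b = box(0, 0, 2 * KM, 5 * KM), box(10 * KM, 0, 12 * KM, 5 * KM)
        assert union_layer([[a], [b]]).area == pytest.approx(a.area + b.area)

    def test_inclusion_exclusion_on_overlap(self):
        # 10 km2 squares overlapping on 4 km2 -> union 16 km2
        a = box(0, 0, 5 * KM, 2 * KM)
        b = box(3 * KM, 0, 8 * KM, 2 * KM)
        assert a.area == b.area == 10 * KM * KM
        assert a.intersection(b).area == 4 * KM * KM
        assert union_layer([[a], [b]]).area == pytest.approx(16 * KM * KM)

    def test_commutative_associative_in_area(self):
        rng = np.random.default_rng(5)
        rects = [
            box(x, y, x + w, y + h)
            for x, y, w, h in rng.uniform(0, 50 * KM, size=(12, 4))
        ]
        a = union_layer([rects[:4], rects[4:]])
        b = union_layer([rects[4:], rects[:4]])
        c = union_layer([rects])
        assert a.area == pytest.approx(b.area) == pytest.approx(c.area)

    def test_empty_input_gives_empty_geometry(self):
        assert union_layer([]).is_empty


class TestCoveragePercent:
    def _quadrant(self):
        grid = build_grid(Territory(boundary=box(0, 0, 20 * KM, 20 * KM)), 20 * KM)
        return grid.quadrants[0]

    def test_full_cover_is_100(self):
        q = self._quadrant()
        assert coverage_percent(q, box(-KM, -KM, 30 * KM, 30 * KM)) == 100.0

    def test_empty_layer_is_0(self):
        q = self._quadrant()
        assert coverage_percent(q, union_layer([])) == 0.0

    def test_quarter_cover_is_25(self):
        q = self._quadrant()
        assert coverage_percent(q, box(0, 0, 10 * KM, 10 * KM)) == pytest.approx(25.0)

    def test_denominator_is_nominal_cell_area_for_boundary_cells(self):
        # territory covers only half the cell; layer covers that half fully
        territory = Territory(boundary=box(0, 0, 10 * KM, 20 * KM))
        grid = build_grid(territory, 20 * KM)
        q = grid.quadrants[0]
        assert coverage_percent(q, territory.boundary) == pytest.approx(50.0)

    def test_monotone_under_layer_growth_and_bounded(self):
        q = self._quadrant()
        rng = np.random.default_rng(9)
        layers = []
        last = 0.0
        for i in range(10):
            x, y = rng.uniform(0, 18 * KM, size=2)
            layers.append(box(x, y, x + 4 * KM, y + 4 * KM))
            pct = coverage_percent(q, union_layer([layers]))
            assert 0.0 <= pct <= 100.0
            assert pct >= last - 1e-9
            last = pct

    def test_table_matches_per_quadrant_calls(self):
        grid = build_grid(Territory(boundary=box(0, 0, 60 * KM, 60 * KM)), 20 * KM)
        layer = union_layer([[box(5 * KM, 5 * KM, 45 * KM, 25 * KM)]])
        table = coverage_percent_table(grid, layer)
        for q in grid:
            assert table[q.id] == pytest.approx(coverage_percent(q, layer))
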