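import itertools
import math

import numpy as np
import pytest

from salamech.errors import InsufficientCoresError, UnreachableError
from salamech.connectivity import (
    all_pair_paths,
    buffer_corridors,
    extract_core_areas,
    least_cost_path,
    paths_to_geojson,
)
from .conftest import make_grid

SQRT2 = math.sqrt(2.0)


def label_grid(labels, cell_size=3.0):
    return make_grid(np.asarray(labels, float), cell_size)


def brute_force_cost(res, cs, src, tgt):
    """Exhaustive minimum-cost simple path by depth-first search with
    admissible pruning (positive step costs)."""
    nr, nc = res.shape
    best = [math.inf]

    def dfs(cell, cost, visited):
        if cost >= best[0]:
            return
        if cell == tgt:
            best[0] = cost
            return
        r, c = cell
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nr and 0 <= c2 < nc) or (r2, c2) in visited:
                continue
            step = 0.5 * (res[r, c] + res[r2, c2]) * cs * (SQRT2 if dr and dc else 1.0)
            visited.add((r2, c2))
            dfs((r2, c2), cost + step, visited)
            visited.remove((r2, c2))

    dfs(src, 0.0, {src})
    return best[0]


class TestExtractCoreAreas:
    def test_minimum_cell_count_is_ceiling(self):
        # 100 m cells: 1 km^2 needs ceil(1e6 / 1e4) = 100 cells
        vals = np.zeros((20, 20))
        vals[:10, :10] = 1  # exactly 100 cells
        vals[15:18, 15:18] = 1  # 9 cells, discarded
        cores = extract_core_areas(make_grid(vals, cell_size=100.0), min_area_km2=1.0)
        assert cores.n_cores == 1
        assert cores.areas_m2[1] == pytest.approx(1e6)

    def test_connectivity_semantics_for_diagonal_touch(self):
        vals = np.zeros((6, 6))
        vals[1, 1] = vals[2, 2] = 1
        grid = make_grid(vals, cell_size=1000.0)
        assert extract_core_areas(grid, 1e-6, connectivity=8).n_cores == 1
        assert extract_core_areas(grid, 1e-6, connectivity=4).n_cores == 2

    def test_empty_raster_gives_zero_patches(self):
        cores = extract_core_areas(make_grid(np.zeros((5, 5))), 1e-9)
        assert cores.n_cores == 0

    def test_labels_ordered_by_descending_area(self):
        vals = np.zeros((10, 10))
        vals[0:2, 0:2] = 1  # 4 cells
        vals[5:9, 5:9] = 1  # 16 cells
        cores = extract_core_areas(make_grid(vals, cell_size=1.0), min_area_km2=1e-9)
        assert cores.areas_m2[1] > cores.areas_m2[2]


class TestLeastCostPath:
    def endpoints(self, shape):
        lab = np.zeros(shape)
        lab[0, 0] = 1
        lab[shape[0] - 1, shape[1] - 1] = 2
        return lab

    def test_uniform_resistance_straight_line(self):
        res = make_grid(np.full((1, 6), 10.0), cell_size=3.0)
        lab = np.zeros((1, 6))
        lab[0, 0], lab[0, 5] = 1, 2
        p = least_cost_path(res, lab, 1, 2)
        assert p.accumulated_cost == pytest.approx(10.0 * 3.0 * 5)
        assert p.path_length == pytest.approx(15.0)
        assert p.euclidean_length == pytest.approx(15.0)

    def test_single_step_average_resistance(self):
        res = make_grid(np.array([[10.0, 30.0]]), cell_size=3.0)
        lab = np.array([[1.0, 2.0]])
        p = least_cost_path(res, lab, 1, 2)
        assert p.accumulated_cost == pytest.approx(20.0 * 3.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            res = rng.integers(1, 10, (5, 5)).astype(float)
            grid = make_grid(res, cell_size=3.0)
            p = least_cost_path(grid, self.endpoints((5, 5)), 1, 2)
            oracle = brute_force_cost(res, 3.0, (0, 0), (4, 4))
            assert p.accumulated_cost == pytest.approx(oracle, abs=1e-9)

    def test_cost_scales_with_resistance_factor(self):
        rng = np.random.default_rng(1)
        res = rng.integers(1, 10, (6, 6)).astype(float)
        lab = self.endpoints((6, 6))
        p1 = least_cost_path(make_grid(res, cell_size=3.0), lab, 1, 2)
        p2 = least_cost_path(make_grid(4.0 * res, cell_size=3.0), lab, 1, 2)
        assert p2.accumulated_cost == pytest.approx(4.0 * p1.accumulated_cost)
        assert p2.cells == p1.cells

    def test_deterministic_under_ties(self):
        res = make_grid(np.ones((7, 7)), cell_size=3.0)
        lab = self.endpoints((7, 7))
        p1 = least_cost_path(res, lab, 1, 2)
        p2 = least_cost_path(res, lab, 1, 2)
        assert p1.cells == p2.cells

    def test_nodata_barrier_unreachable(self):
        vals = np.ones((5, 5))
        mask = np.zeros((5, 5), bool)
        mask[:, 2] = True  # impassable column
        res = make_grid(vals, cell_size=3.0, nodata=mask)
        lab = self.endpoints((5, 5))
        with pytest.raises(UnreachableError):
            least_cost_path(res, lab, 1, 2)

    def test_same_label_rejected(self):
        res = make_grid(np.ones((4, 4)))
        with pytest.raises(ValueError):
            least_cost_path(res, self.endpoints((4, 4)), 1, 1)

    def test_zero_cost_inside_source_patch(self):
        # a 2-cell source patch: the nearer cell seeds the path
        res = make_grid(np.full((1, 5), 10.0), cell_size=3.0)
        lab = np.array([[1.0, 1.0, 0.0, 0.0, 2.0]])
        p = least_cost_path(res, lab, 1, 2)
        assert p.accumulated_cost == pytest.approx(10.0 * 3.0 * 3)


class TestAllPairPaths:
    def three_core_setup(self):
        vals = np.zeros((9, 9))
        vals[0, 0] = vals[0, 8] = vals[8, 4] = 1
        cores = extract_core_areas(make_grid(vals, cell_size=3.0), min_area_km2=1e-9)
        res = make_grid(np.ones((9, 9)), cell_size=3.0)
        return res, cores

    def test_complete_graph_pair_count(self):
        res, cores = self.three_core_setup()
        paths, failures = all_pair_paths(res, cores)
        assert len(paths) == 3 and not failures

    def test_mst_keeps_spanning_edges(self):
        res, cores = self.three_core_setup()
        paths, _ = all_pair_paths(res, cores, mode="mst")
        assert len(paths) == 2

    def test_symmetric_cost_between_two_cores(self):
        res, cores = self.three_core_setup()
        a = least_cost_path(res, cores, 1, 2)
        b = least_cost_path(res, cores, 2, 1)
        assert a.accumulated_cost == pytest.approx(b.accumulated_cost)
        assert a.path_length == pytest.approx(b.path_length)

    def test_fewer_than_two_cores_rejected(self):
        vals = np.zeros((5, 5))
        vals[0, 0] = 1
        cores = extract_core_areas(make_grid(vals), min_area_km2=1e-12)
        with pytest.raises(InsufficientCoresError):
            all_pair_paths(make_grid(np.ones((5, 5))), cores)


class TestBufferCorridors:
    def one_cell_path(self, grid):
        from salamech.connectivity import LeastCostPath

        return LeastCostPath(1, 2, [(5, 5)], 0.0, 0.0, 0.0)

    def test_zero_radius_equals_path_cells(self):
        grid = make_grid(np.ones((11, 11)), cell_size=3.0)
        out = buffer_corridors([self.one_cell_path(grid)], grid, radius_m=0.0)
        assert out.corridor_mask.values.sum() == 1
        assert out.corridor_mask.values[5, 5]

    def test_disk_by_brute_force_distance(self):
        grid = make_grid(np.ones((11, 11)), cell_size=3.0)
        out = buffer_corridors([self.one_cell_path(grid)], grid, radius_m=6.0)
        rr, cc = np.mgrid[0:11, 0:11]
        expected = np.hypot(rr - 5, cc - 5) * 3.0 <= 6.0 + 1e-9
        np.testing.assert_array_equal(out.corridor_mask.values.astype(bool), expected)

    def test_union_over_paths(self):
        from salamech.connectivity import LeastCostPath

        grid = make_grid(np.ones((9, 9)), cell_size=3.0)
        p1 = LeastCostPath(1, 2, [(4, 3)], 0, 0, 0)
        p2 = LeastCostPath(2, 3, [(4, 5)], 0, 0, 0)
        out = buffer_corridors([p1, p2], grid, radius_m=3.0)
        # the midpoint cell is near both paths but counted once
        assert out.corridor_mask.values[4, 4]
        assert out.corridor_mask.values.sum() == np.unique(
            np.argwhere(out.corridor_mask.values), axis=0).shape[0]


def test_geojson_export_structure():
    grid = make_grid(np.ones((5, 5)), cell_size=3.0)
    lab = np.zeros((5, 5))
    lab[0, 0], lab[4, 4] = 1, 2
    p = least_cost_path(grid, lab, 1, 2)
    gj = paths_to_geojson([p], grid)
    assert gj["type"] == "FeatureCollection"
    feat = gj["features"][0]
    assert feat["geometry"]["type"] == "LineString"
    assert feat["properties"]["source"] == 1
    assert len(feat["geometry"]["coordinates"]) == len(p.cells)
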