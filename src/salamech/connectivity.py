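"""Core areas, least-cost paths, and buffered activity corridors.

Core areas are contiguous patches of highly suitable habitat above a
minimum area.  Least-cost paths run over the resistance raster with the
standard cost-distance step rule: moving between neighboring cells costs
the mean of their resistances times the center-to-center distance
(cell_size, times sqrt(2) for diagonal moves).  Patches act as zero-cost
super-nodes: every cell of the source patch seeds the multi-source Dijkstra
at zero accumulated cost, and the search stops at the first cell of the
target patch.  Tie-breaking is deterministic (lexicographic neighbor order
N, NE, E, SE, S, SW, W, NW with stable queue insertion), so outputs are
reproducible.

Corridors are the paths buffered by a Euclidean distance (300 m default,
the upper bound of typical plethodontid movements).
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage import measure

from .errors import InsufficientCoresError, UnreachableError
from .raster import RasterGrid

# lexicographic neighbor order: N, NE, E, SE, S, SW, W, NW
NEIGHBORS_8 = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_SQRT2 = math.sqrt(2.0)


@dataclass
class CoreAreaSet:
    """Labeled >= min-area patches of suitable habitat (0 = background)."""

    labels: RasterGrid  # integer labels
    areas_m2: dict[int, float]
    min_area_km2: float
    connectivity: int = 8

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.areas_m2)

    @property
    def n_cores(self) -> int:
        return len(self.areas_m2)


@dataclass
class LeastCostPath:
    source_label: int
    target_label: int
    cells: list[tuple[int, int]]
    accumulated_cost: float  # resistance * meters
    path_length: float  # meters along the path
    euclidean_length: float  # meters endpoint to endpoint


@dataclass
class CorridorSet:
    paths: list[LeastCostPath]
    corridor_mask: RasterGrid  # boolean
    buffer_radius: float


def extract_core_areas(suitable: RasterGrid, min_area_km2: float = 1.0,
                       connectivity: int = 8) -> CoreAreaSet:
    """Connected-component labeling with a minimum-area screen.

    Components smaller than ceil(min_area * 1e6 / cell_area) cells are
    discarded; survivors are relabeled 1..K by descending area (ties by
    original label).  An empty result is legitimate, not an error.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    arr = suitable.values.astype(bool) & suitable.valid
    lab = measure.label(arr, connectivity=2 if connectivity == 8 else 1)
    cell_area = suitable.cell_size**2
    min_cells = math.ceil(min_area_km2 * 1e6 / cell_area)
    counts = np.bincount(lab.ravel())
    keep = [(int(counts[l]), l) for l in range(1, len(counts)) if counts[l] >= min_cells]
    keep.sort(key=lambda t: (-t[0], t[1]))
    out = np.zeros(lab.shape, dtype=np.int32)
    areas = {}
    for new_id, (n_cells, old) in enumerate(keep, start=1):
        out[lab == old] = new_id
        areas[new_id] = n_cells * cell_area
    return CoreAreaSet(suitable.like(out, suitable.nodata_mask.copy()),
                       areas, min_area_km2, connectivity)


def _label_array(cores) -> np.ndarray:
    if isinstance(cores, CoreAreaSet):
        return cores.labels.values.astype(np.int64)
    if isinstance(cores, RasterGrid):
        return cores.values.astype(np.int64)
    return np.asarray(cores, dtype=np.int64)


def paths_from_source(resistance: RasterGrid, cores, source_label: int,
                      target_labels) -> dict[int, LeastCostPath]:
    """Least-cost paths from one patch to several target patches in a single
    multi-source Dijkstra sweep.

    Returns a dict target_label -> path for the targets that were reached;
    unreached targets are simply absent.
    """
    labels = _label_array(cores)
    if labels.shape != resistance.shape:
        raise ValueError("label grid shape differs from resistance grid")
    targets = {int(t) for t in target_labels}
    if source_label in targets:
        raise ValueError("source and target labels must differ")
    res = resistance.values.astype(float)
    passable = resistance.valid
    nr, nc = res.shape
    cs = resistance.cell_size

    src = (labels == source_label) & passable
    if not src.any():
        raise ValueError("source label absent (or fully on nodata)")
    targets = {t for t in targets if ((labels == t) & passable).any()}

    dist = np.full(nr * nc, np.inf)
    pred = np.full(nr * nc, -1, dtype=np.int64)
    settled = np.zeros(nr * nc, dtype=bool)
    counter = itertools.count()
    heap = []
    for r, c in np.argwhere(src):  # row-major seeding
        idx = int(r) * nc + int(c)
        dist[idx] = 0.0
        heapq.heappush(heap, (0.0, next(counter), idx))

    goals: dict[int, int] = {}
    flat_labels = labels.ravel()
    flat_res = res.ravel()
    flat_pass = passable.ravel()
    while heap and len(goals) < len(targets):
        d, _, idx = heapq.heappop(heap)
        if settled[idx]:
            continue
        settled[idx] = True
        lab = flat_labels[idx]
        if lab in targets and lab not in goals:
            goals[int(lab)] = idx
            if len(goals) == len(targets):
                break
        r, c = divmod(idx, nc)
        ra = flat_res[idx]
        for dr, dc in NEIGHBORS_8:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nr and 0 <= c2 < nc):
                continue
            idx2 = r2 * nc + c2
            if settled[idx2] or not flat_pass[idx2]:
                continue
            step = 0.5 * (ra + flat_res[idx2]) * cs * (_SQRT2 if dr and dc else 1.0)
            nd = d + step
            if nd < dist[idx2]:
                dist[idx2] = nd
                pred[idx2] = idx
                heapq.heappush(heap, (nd, next(counter), idx2))

    out: dict[int, LeastCostPath] = {}
    for tlab, goal in goals.items():
        cells = []
        cur = goal
        while cur != -1:
            cells.append((int(cur) // nc, int(cur) % nc))
            cur = pred[cur]
        cells.reverse()
        path_len = 0.0
        for (r1, c1), (r2, c2) in zip(cells, cells[1:]):
            path_len += cs * (_SQRT2 if (r1 != r2 and c1 != c2) else 1.0)
        x1, y1 = resistance.cell_center(cells[0][0], cells[0][1])
        x2, y2 = resistance.cell_center(cells[-1][0], cells[-1][1])
        euclid = math.hypot(float(x2) - float(x1), float(y2) - float(y1))
        out[tlab] = LeastCostPath(source_label, tlab, cells,
                                  float(dist[goal]), path_len, euclid)
    return out


def least_cost_path(resistance: RasterGrid, cores, source_label: int,
                    target_label: int) -> LeastCostPath:
    """Minimum accumulated-cost route between two labeled patches.

    ``cores`` may be a :class:`CoreAreaSet`, a label RasterGrid, or a plain
    integer label array on the resistance grid.  Nodata resistance cells are
    barriers.  Raises :class:`UnreachableError` if no route exists.
    """
    labels = _label_array(cores)
    if not ((labels == target_label) & resistance.valid).any():
        raise ValueError("target label absent (or fully on nodata)")
    found = paths_from_source(resistance, cores, source_label, [target_label])
    if target_label not in found:
        raise UnreachableError(source_label, target_label)
    return found[target_label]


def all_pair_paths(resistance: RasterGrid, cores: CoreAreaSet,
                   mode: str = "complete"):
    """One least-cost path per unordered core pair.

    ``mode='complete'`` keeps every pair; ``mode='mst'`` keeps only the
    edges of the cost-weighted minimum spanning network.  Per-pair
    unreachability is reported in the returned failure list, not fatal.
    Returns ``(paths, failures)``.
    """
    ids = cores.label_ids
    if len(ids) < 2:
        raise InsufficientCoresError(f"need >= 2 cores, found {len(ids)}")
    paths, failures = [], []
    by_pair = {}
    for i, a in enumerate(ids[:-1]):
        rest = ids[i + 1:]
        found = paths_from_source(resistance, cores, a, rest)
        for b in rest:
            if b in found:
                paths.append(found[b])
                by_pair[(a, b)] = found[b]
            else:
                failures.append((a, b, f"core {b} is unreachable from core {a}"))
    if mode == "mst" and paths:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import minimum_spanning_tree

        k = len(ids)
        pos = {l: i for i, l in enumerate(ids)}
        mat = np.zeros((k, k))
        for (a, b), p in by_pair.items():
            mat[pos[a], pos[b]] = p.accumulated_cost + 1e-12  # keep zero costs as edges
        tree = minimum_spanning_tree(csr_matrix(mat)).tocoo()
        kept = set()
        for i, j in zip(tree.row, tree.col):
            a, b = ids[min(i, j)], ids[max(i, j)]
            kept.add((a, b))
        paths = [by_pair[pair] for pair in sorted(kept)]
    elif mode not in ("complete", "mst"):
        raise ValueError("mode must be 'complete' or 'mst'")
    return paths, failures


def buffer_corridors(paths: list[LeastCostPath], grid: RasterGrid,
                     radius_m: float = 300.0) -> CorridorSet:
    """Union of paths buffered by a Euclidean (cell-center) distance."""
    if radius_m < 0:
        raise ValueError("radius must be >= 0")
    path_mask = np.zeros(grid.shape, dtype=bool)
    for p in paths:
        for r, c in p.cells:
            path_mask[r, c] = True
    if not path_mask.any():
        corridor = np.zeros(grid.shape, dtype=bool)
    else:
        dist = distance_transform_edt(~path_mask, sampling=grid.cell_size)
        corridor = dist <= radius_m + 1e-9
    return CorridorSet(paths, grid.like(corridor, grid.nodata_mask.copy()), radius_m)


def paths_to_geojson(paths: list[LeastCostPath], grid: RasterGrid) -> dict:
    """Paths as GeoJSON LineStrings with cost/length properties."""
    features = []
    for p in paths:
        rows = np.array([rc[0] for rc in p.cells])
        cols = np.array([rc[1] for rc in p.cells])
        x, y = grid.cell_center(rows, cols)
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(xi), float(yi)] for xi, yi in zip(x, y)],
            },
            "properties": {
                "source": p.source_label,
                "target": p.target_label,
                "accumulated_cost": p.accumulated_cost,
                "path_length_m": p.path_length,
                "euclidean_length_m": p.euclidean_length,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)
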