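"""Patch-based fragmentation metrics within activity corridors.

The highly suitable habitat is clipped to the corridor mask, patches are
labeled, and three standard landscape metrics are reported:

* mean Euclidean nearest-neighbor distance (ENN, m) between patches,
  measured center-to-center between boundary cells;
* patch density (PD, patches per hectare of corridor);
* mean perimeter-area ratio (PA, 1/m), with perimeter counted as exposed
  cell faces (patch-to-nonpatch and patch-to-grid-edge) times cell size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .errors import EmptyDomainError
from .raster import RasterGrid, require_same_grid
from .connectivity import CorridorSet


@dataclass
class PatchSet:
    labels: RasterGrid  # integer labels, 0 = background
    areas_m2: dict[int, float]
    perimeters_m: dict[int, float]
    boundary_cells: dict[int, np.ndarray]  # (k, 2) row/col arrays
    connectivity: int = 8

    @property
    def n_patches(self) -> int:
        return len(self.areas_m2)


@dataclass
class FragmentationReport:
    enn_mean: float  # m (NaN when < 2 patches)
    enn_sd: float
    pd: float  # patches per hectare
    pa_mean: float  # 1/m (NaN when no patches)
    n_patches: int
    landscape_area_ha: float


def clip_to_corridor(suitable: RasterGrid, corridor: CorridorSet | RasterGrid) -> RasterGrid:
    """Logical AND of the suitable mask and the corridor mask."""
    cmask = corridor.corridor_mask if isinstance(corridor, CorridorSet) else corridor
    require_same_grid(suitable, cmask)
    vals = suitable.values.astype(bool) & cmask.values.astype(bool) & suitable.valid & cmask.valid
    return suitable.like(vals, suitable.nodata_mask | cmask.nodata_mask)


def label_patches(habitat: RasterGrid, connectivity: int = 8) -> PatchSet:
    """Connected components with per-patch area, perimeter and boundary cells."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    arr = habitat.values.astype(bool) & habitat.valid
    lab = measure.label(arr, connectivity=2 if connectivity == 8 else 1)
    cs = habitat.cell_size
    cell_area = cs * cs
    counts = np.bincount(lab.ravel())
    n_labels = len(counts) - 1

    # shared faces between same-label 4-neighbors
    shared = np.zeros(len(counts), dtype=np.int64)
    horiz = (lab[:, :-1] == lab[:, 1:]) & (lab[:, :-1] > 0)
    vert = (lab[:-1, :] == lab[1:, :]) & (lab[:-1, :] > 0)
    if horiz.any():
        shared += np.bincount(lab[:, :-1][horiz].ravel(), minlength=len(counts))
    if vert.any():
        shared += np.bincount(lab[:-1, :][vert].ravel(), minlength=len(counts))

    # boundary cells: any 4-neighbor outside the patch (or the grid edge)
    padded = np.pad(lab, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    boundary = (core > 0) & (
        (padded[:-2, 1:-1] != core) | (padded[2:, 1:-1] != core)
        | (padded[1:-1, :-2] != core) | (padded[1:-1, 2:] != core)
    )

    areas, perims, bounds = {}, {}, {}
    for l in range(1, n_labels + 1):
        if counts[l] == 0:
            continue
        areas[l] = float(counts[l]) * cell_area
        perims[l] = float(4 * counts[l] - 2 * shared[l]) * cs
        bounds[l] = np.argwhere(boundary & (lab == l))
    return PatchSet(habitat.like(lab, habitat.nodata_mask.copy()),
                    areas, perims, bounds, connectivity)


def enn_mean(patches: PatchSet) -> tuple[float, float]:
    """Mean and SD over patches of the nearest-neighbor distance (m).

    Per patch: the minimum center-to-center distance from its boundary
    cells to any other patch's boundary cells.  Undefined (NaN, NaN) with
    fewer than two patches, matching the metric's convention of a missing
    value.
    """
    ids = sorted(patches.areas_m2)
    if len(ids) < 2:
        return (float("nan"), float("nan"))
    cs = patches.labels.cell_size
    pts = {l: patches.boundary_cells[l].astype(float) * cs for l in ids}
    nearest = []
    for l in ids:
        others = np.vstack([pts[m] for m in ids if m != l])
        tree = cKDTree(others)
        d, _ = tree.query(pts[l], k=1)
        nearest.append(float(np.min(d)))
    arr = np.asarray(nearest)
    return float(arr.mean()), float(arr.std(ddof=0))


def patch_density(patches: PatchSet, landscape_mask: RasterGrid) -> float:
    """Patches per hectare of landscape (the corridor mask by convention)."""
    area_m2 = float((landscape_mask.values.astype(bool) & landscape_mask.valid).sum())
    area_m2 *= landscape_mask.cell_size**2
    if area_m2 <= 0:
        raise EmptyDomainError("landscape mask has zero area")
    return patches.n_patches / (area_m2 / 1e4)


def perimeter_area_ratio(patches: PatchSet) -> float:
    """Mean over patches of perimeter / area (1/m); NaN with no patches."""
    if patches.n_patches == 0:
        return float("nan")
    ratios = [patches.perimeters_m[l] / patches.areas_m2[l] for l in patches.areas_m2]
    return float(np.mean(ratios))


def compute_fragmentation(suitable: RasterGrid, corridor: CorridorSet,
                          connectivity: int = 8) -> FragmentationReport:
    """Clip suitable habitat to the corridor and report ENN / PD / PA."""
    clipped = clip_to_corridor(suitable, corridor)
    patches = label_patches(clipped, connectivity)
    mean_enn, sd_enn = enn_mean(patches)
    lmask = corridor.corridor_mask
    area_ha = float((lmask.values.astype(bool) & lmask.valid).sum()) * lmask.cell_size**2 / 1e4
    pd_val = patch_density(patches, lmask) if area_ha > 0 else float("nan")
    return FragmentationReport(
        enn_mean=mean_enn,
        enn_sd=sd_enn,
        pd=pd_val,
        pa_mean=perimeter_area_ratio(patches),
        n_patches=patches.n_patches,
        landscape_area_ha=area_ha,
    )
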