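"""Spatio-temporal agreement between suitability and resistance surfaces.

Agreement is measured by Spearman's rho on values extracted at random sample
points.  Because high suitability and *low* resistance both indicate good
conditions, negative correlations mean model agreement and positive ones
disagreement.

The multi-resolution analysis aggregates both surfaces to a ladder of
coarser cell sizes (block mean), maps the same sample points to the coarse
cells, collapses duplicates (points landing in one coarse cell), and
re-computes rho on the survivors; a plateau of the |rho|-versus-resolution
curve marks the convergence resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyDomainError,
    InvalidResolutionError,
    UndefinedCorrelationError,
)
from .raster import RasterGrid, require_same_grid
from .sdm import SuitabilitySurface


@dataclass
class SamplePoints:
    coordinates: np.ndarray  # (n, 2) of x, y
    seed: int
    mask_descriptor: str = "full"

    @property
    def n(self) -> int:
        return len(self.coordinates)


@dataclass
class AgreementTable:
    rows: pd.DataFrame  # species, season, period, domain, rho, n_effective


@dataclass
class ResolutionCurve:
    resolutions: list[float]
    rho: list[float | None]
    n_effective: list[int]

    def defined(self):
        return [(r, rho, n) for r, rho, n in zip(self.resolutions, self.rho, self.n_effective)
                if rho is not None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "resolution_m": self.resolutions,
            "rho": [np.nan if r is None else r for r in self.rho],
            "n_effective": self.n_effective,
        })


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (average ranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 pairs")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise UndefinedCorrelationError("zero rank variance")
    return float(stats.spearmanr(x, y).statistic)


def sample_within(mask: RasterGrid, n: int, seed: int,
                  descriptor: str = "mask") -> SamplePoints:
    """Uniform sample of distinct mask cells (without replacement), points at
    cell centers; n is capped at the number of available cells."""
    cells = np.flatnonzero(mask.values.astype(bool) & mask.valid)
    if cells.size == 0:
        raise EmptyDomainError("sampling mask is empty")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 41])
    take = min(int(n), cells.size)
    chosen = rng.choice(cells, size=take, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    x, y = mask.cell_center(rows, cols)
    return SamplePoints(np.column_stack([x, y]), seed, descriptor)


def _extract_pairs(a: RasterGrid, b: RasterGrid, points: SamplePoints):
    va, oka = a.values_at(points.coordinates)
    vb, okb = b.values_at(points.coordinates)
    ok = oka & okb
    return va[ok], vb[ok]


def correlate_surfaces(sdm: SuitabilitySurface | RasterGrid, mech: RasterGrid,
                       points: SamplePoints) -> float:
    """rho between suitability and a mechanistic layer at the sample points.

    Serves the full-resistance, SMR-only and VPD-only comparisons alike;
    negative rho = agreement.
    """
    sgrid = sdm.prob if isinstance(sdm, SuitabilitySurface) else sdm
    require_same_grid(sgrid, mech)
    va, vb = _extract_pairs(sgrid, mech, points)
    if len(va) < 3:
        raise UndefinedCorrelationError("fewer than 3 valid pairs")
    return spearman_rho(va, vb)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _coarse_shape(grid: RasterGrid, target: float) -> tuple[int, int]:
    nr, nc = grid.shape
    return (
        int(math.ceil(nr * grid.cell_size / target)),
        int(math.ceil(nc * grid.cell_size / target)),
    )


def _overlap_matrix(n_fine: int, cs: float, n_coarse: int, target: float) -> np.ndarray:
    """1-D overlap lengths between fine intervals [i*cs,(i+1)*cs] and coarse
    intervals [I*t,(I+1)*t]; rows = coarse, cols = fine."""
    W = np.zeros((n_coarse, n_fine))
    for i in range(n_fine):
        a, b = i * cs, (i + 1) * cs
        lo = int(a // target)
        hi = min(int(math.floor((b - 1e-12) / target)), n_coarse - 1)
        for big in range(lo, hi + 1):
            W[big, i] = max(0.0, min(b, (big + 1) * target) - max(a, big * target))
    return W


def aggregate_mean(raster: RasterGrid, target_cell_size: float,
                   method: str = "center") -> RasterGrid:
    """Block-mean aggregation to a coarser grid anchored at the raster origin.

    ``method='center'`` assigns each fine cell to the coarse cell containing
    its center; ``method='area'`` weights fine cells by exact overlap area.
    A coarse cell is nodata iff all contributing fine cells are nodata.
    """
    cs = raster.cell_size
    if target_cell_size < cs - 1e-9:
        raise InvalidResolutionError(
            f"target {target_cell_size} m finer than source {cs} m")
    if abs(target_cell_size - cs) <= 1e-9:
        return raster.copy()
    ncr, ncc = _coarse_shape(raster, target_cell_size)
    valid = raster.valid
    vals = np.where(valid, raster.values, 0.0)
    if method == "center":
        nr, nc = raster.shape
        ri = np.floor((np.arange(nr) + 0.5) * cs / target_cell_size).astype(int)
        ci = np.floor((np.arange(nc) + 0.5) * cs / target_cell_size).astype(int)
        ri = np.clip(ri, 0, ncr - 1)
        ci = np.clip(ci, 0, ncc - 1)
        flat = ri[:, None] * ncc + ci[None, :]
        sums = np.bincount(flat.ravel(), weights=vals.ravel(), minlength=ncr * ncc)
        cnts = np.bincount(flat.ravel(), weights=valid.astype(float).ravel(),
                           minlength=ncr * ncc)
    elif method == "area":
        Wr = _overlap_matrix(raster.shape[0], cs, ncr, target_cell_size)
        Wc = _overlap_matrix(raster.shape[1], cs, ncc, target_cell_size)
        sums = (Wr @ vals @ Wc.T).ravel()
        cnts = (Wr @ valid.astype(float) @ Wc.T).ravel()
    else:
        raise ValueError("method must be 'center' or 'area'")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnts > 0, sums / np.where(cnts > 0, cnts, 1.0), 0.0)
    mask = (cnts <= 0).reshape(ncr, ncc)
    return RasterGrid(mean.reshape(ncr, ncc), target_cell_size, raster.origin, mask)


# ---------------------------------------------------------------------------
# Multi-resolution agreement
# ---------------------------------------------------------------------------


def default_resolution_ladder(native: float, extent_m: float) -> list[float]:
    """Doubling ladder from the native resolution up to ~1/8 of the extent."""
    out = [native]
    r = native * 2
    while r <= extent_m / 8.0:
        out.append(r)
        r *= 2
    return out


def multiresolution_agreement(sdm: SuitabilitySurface | RasterGrid, mech: RasterGrid,
                              points: SamplePoints, resolutions: list[float],
                              method: str = "center") -> ResolutionCurve:
    """rho at each resolution after aggregation and duplicate-point removal.

    One point set is reused across resolutions; points whose coarse cell was
    already sampled are dropped (duplicate removal), so ``n_effective`` is
    non-increasing with coarsening.  Resolutions leaving fewer than 3
    distinct valid cells yield an undefined row (rho None); the curve
    continues.
    """
    sgrid = sdm.prob if isinstance(sdm, SuitabilitySurface) else sdm
    require_same_grid(sgrid, mech)
    if any(b <= a for a, b in zip(resolutions, resolutions[1:])):
        raise InvalidResolutionError("resolutions must be strictly increasing")
    rhos: list[float | None] = []
    n_eff: list[int] = []
    for res in resolutions:
        a = aggregate_mean(sgrid, res, method)
        b = aggregate_mean(mech, res, method)
        rows, cols = a.point_to_rc(points.coordinates[:, 0], points.coordinates[:, 1])
        nr, nc = a.shape
        inside = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
        flat = rows[inside] * nc + cols[inside]
        _, first = np.unique(flat, return_index=True)
        cells = flat[np.sort(first)]
        r, c = cells // nc, cells % nc
        ok = a.valid[r, c] & b.valid[r, c]
        va, vb = a.values[r, c][ok], b.values[r, c][ok]
        n_eff.append(int(len(va)))
        if len(va) < 3:
            rhos.append(None)
            continue
        try:
            rhos.append(spearman_rho(va, vb))
        except UndefinedCorrelationError:
            rhos.append(None)
    return ResolutionCurve(list(resolutions), rhos, n_eff)


def convergence_resolution(curve: ResolutionCurve, epsilon: float = 0.01,
                           window: int = 2) -> float | None:
    """Smallest resolution after which |rho| changes by < epsilon for
    ``window`` consecutive steps of the defined part of the curve; None if
    the curve never settles."""
    defined = curve.defined()
    if len(defined) < window + 1:
        return None
    absrho = [abs(r) for _, r, _ in defined]
    res = [r for r, _, _ in defined]
    for i in range(len(absrho) - window):
        steps = [abs(absrho[j + 1] - absrho[j]) for j in range(i, i + window)]
        if all(s < epsilon for s in steps):
            return res[i]
    return None


def agreement_table(entries) -> AgreementTable:
    """Assemble (species, season, period, domain, rho, n_effective) rows."""
    df = pd.DataFrame(entries,
                      columns=["species", "season", "period", "domain", "rho", "n_effective"])
    return AgreementTable(df)


def plot_resolution_curves(curves: dict[str, ResolutionCurve], path=None):
    """|rho| versus resolution, one line per labelled curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        pts = curve.defined()
        ax.plot([p[0] for p in pts], [abs(p[1]) for p in pts], marker="o", label=label)
    ax.set_xlabel("spatial resolution (m)")
    ax.set_ylabel("|Spearman's rho|")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
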