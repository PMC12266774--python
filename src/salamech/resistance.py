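"""Resistance-to-surface-activity surfaces and high-priority areas.

The mechanistic surface combines the two physiological costs: standard
metabolic rate (energetic cost of maintenance) and vapor pressure deficit
(drying cost of being surface-active).  Each layer is min-max rescaled to
[0, 1] *within its season and period*, the rescaled layers are summed and
multiplied by 100, giving a 0-200 resistance raster: low values mean lower
resistance to potential surface activity.

High-priority areas (HPA) are the cells where both raw layers sit at or
below their medians, with medians computed inside the species' elevational
range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyDomainError
from .raster import RasterGrid, combined_mask, require_same_grid
from .physiology import SmrSurface
from .moisture import VpdSurface


@dataclass
class ResistanceSurface:
    resistance: RasterGrid  # [0, 200]
    rescaled_smr: RasterGrid  # [0, 1]
    rescaled_vpd: RasterGrid  # [0, 1]
    species: str = "synthetic"
    season: str = "summer"
    period_label: str = "2010"


@dataclass
class HighPriorityArea:
    mask: RasterGrid  # boolean
    smr_median: float
    vpd_median: float
    season: str = "summer"
    period_label: str = "2010"


def rescale01(layer: RasterGrid) -> RasterGrid:
    """(x - min) / (max - min) over non-nodata cells; constant layers map
    to all zeros (declared lowest-resistance convention)."""
    if not np.any(layer.valid):
        raise EmptyDomainError("rescale01 needs at least one non-nodata cell")
    vals = layer.masked_values()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        out = np.zeros(layer.shape)
    else:
        out = (layer.values - lo) / (hi - lo)
    out = np.where(layer.valid, out, 0.0)
    return layer.like(out)


def build_resistance(smr: SmrSurface, vpd: VpdSurface,
                     smr_weight: float = 1.0, vpd_weight: float = 1.0) -> ResistanceSurface:
    """resistance = 100 * (rescale01(smr) + rescale01(vpd)), range [0, 200].

    Weights default to the equal 1:1 combination; the rescale step makes the
    result invariant to positive affine transforms of either raw layer.
    """
    require_same_grid(smr.vo2, vpd.vpd)
    if smr.season != vpd.season or smr.period_label != vpd.period_label:
        raise ValueError("SMR and VPD surfaces must share season and period")
    r_smr = rescale01(smr.vo2)
    r_vpd = rescale01(vpd.vpd)
    mask = combined_mask(smr.vo2, vpd.vpd)
    vals = 100.0 * (smr_weight * r_smr.values + vpd_weight * r_vpd.values)
    return ResistanceSurface(
        resistance=smr.vo2.like(vals, mask),
        rescaled_smr=r_smr,
        rescaled_vpd=r_vpd,
        species=smr.species,
        season=smr.season,
        period_label=smr.period_label,
    )


def delineate_hpa(smr: SmrSurface, vpd: VpdSurface, elevation: RasterGrid,
                  range_m: tuple[float, float] = (665.0, 2025.0)) -> HighPriorityArea:
    """Cells with SMR <= median and VPD <= median inside the elevational range.

    Medians are computed over the in-range, non-nodata cells only.
    """
    require_same_grid(smr.vo2, vpd.vpd, elevation)
    lo, hi = range_m
    in_range = (
        (elevation.values >= lo) & (elevation.values <= hi)
        & elevation.valid & smr.vo2.valid & vpd.vpd.valid
    )
    if not np.any(in_range):
        raise EmptyDomainError(f"no cells inside elevational range {range_m}")
    smr_med = float(np.median(smr.vo2.values[in_range]))
    vpd_med = float(np.median(vpd.vpd.values[in_range]))
    mask = in_range & (smr.vo2.values <= smr_med) & (vpd.vpd.values <= vpd_med)
    grid = elevation.like(mask, ~in_range)
    return HighPriorityArea(grid, smr_med, vpd_med, smr.season, smr.period_label)


def hpa_season_consistency(hpas: dict[str, HighPriorityArea]) -> dict:
    """Cross-season HPA report: per-season fractions plus the intersection
    and union of the seasonal masks (all relative to in-range cells)."""
    masks = {s: h.mask.values.astype(bool) for s, h in hpas.items()}
    domain = np.logical_or.reduce([h.mask.valid for h in hpas.values()])
    n_domain = int(domain.sum())
    if n_domain == 0:
        raise EmptyDomainError("no in-range cells across seasons")
    inter = np.logical_and.reduce(list(masks.values()))
    union = np.logical_or.reduce(list(masks.values()))
    return {
        "per_season_fraction": {s: float(m.sum()) / n_domain for s, m in masks.items()},
        "all_season_fraction": float(inter.sum()) / n_domain,
        "any_season_fraction": float(union.sum()) / n_domain,
    }
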