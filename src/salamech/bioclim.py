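"""Temperature-based bioclimatic variables and seasonal means.

Only monthly minimum/maximum temperature enters the study, so the eleven
variables derived here are the temperature bioclims BIO1-BIO11.  The two
precipitation-conditioned quarter variables (BIO8, BIO9) have no
precipitation to condition on and fall back to the warmest/coldest quarter,
coinciding with BIO10/BIO11; they are kept as distinct slots so a different
variable list can be configured.

Quarters are any three *consecutive* months within the available window
(no calendar wraparound - only growing-season months are modelled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientMonthsError
from .raster import RasterGrid, combined_mask
from .synthetic import MonthlyClimate

BIOCLIM_CODES = tuple(f"BIO{i}" for i in range(1, 12))

SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
}


@dataclass
class BioclimStack:
    """Ordered map of bioclim code -> raster, plus provenance."""

    variables: dict[str, RasterGrid]
    season_window: tuple[int, ...]
    period_label: str = "2010"

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.variables)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.variables.values()))

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_cells, n_vars) value matrix over all cells + joint valid mask."""
        grids = list(self.variables.values())
        valid = ~combined_mask(*grids)
        X = np.column_stack([g.values.ravel() for g in grids])
        return X, valid.ravel()

    def values_at(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(n_points, n_vars) predictor matrix at map-coordinate points."""
        cols, oks = [], []
        for g in self.variables.values():
            v, ok = g.values_at(points)
            cols.append(v)
            oks.append(ok)
        X = np.column_stack(cols)
        ok = np.logical_and.reduce(oks)
        return X, ok


@dataclass
class SeasonalMeans:
    season: str
    tmin_mean: RasterGrid
    tmax_mean: RasterGrid
    tmean: RasterGrid


def _monthly_means(climate: MonthlyClimate) -> dict[int, np.ndarray]:
    return {m: (climate.tmin[m].values + climate.tmax[m].values) / 2.0 for m in climate.months}


def _quarters(months: tuple[int, ...]) -> list[tuple[int, int, int]]:
    """All runs of three consecutive calendar months in the window."""
    out = []
    ms = sorted(months)
    for a, b, c in zip(ms, ms[1:], ms[2:]):
        if b == a + 1 and c == b + 1:
            out.append((a, b, c))
    return out


def derive_bioclim(climate: MonthlyClimate, period_label: str | None = None,
                   population_sd: bool = True) -> BioclimStack:
    """Derive BIO1-BIO11 from a monthly min/max temperature stack.

    BIO1  mean of monthly mean temperatures
    BIO2  mean diurnal range, mean over months of (tmax - tmin)
    BIO3  isothermality, 100 * BIO2 / BIO7
    BIO4  temperature seasonality, 100 * SD of monthly means
          (population SD by default, the dominant bioclim convention)
    BIO5  max tmax of warmest month
    BIO6  min tmin of coldest month
    BIO7  annual range, BIO5 - BIO6
    BIO8/BIO10  mean temperature of the warmest quarter
    BIO9/BIO11  mean temperature of the coldest quarter
    """
    if len(climate.months) < 3:
        raise InsufficientMonthsError("need at least 3 months of climate data")
    grids = [climate.tmin[m] for m in climate.months] + [climate.tmax[m] for m in climate.months]
    mask = combined_mask(*grids)
    ref = climate.grid

    means = _monthly_means(climate)
    mean_stack = np.stack([means[m] for m in climate.months])
    tmin_stack = np.stack([climate.tmin[m].values for m in climate.months])
    tmax_stack = np.stack([climate.tmax[m].values for m in climate.months])
    drange_stack = tmax_stack - tmin_stack

    bio1 = mean_stack.mean(axis=0)
    bio2 = drange_stack.mean(axis=0)
    bio4 = 100.0 * mean_stack.std(axis=0, ddof=0 if population_sd else 1)
    bio5 = tmax_stack.max(axis=0)
    bio6 = tmin_stack.min(axis=0)
    bio7 = bio5 - bio6

    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = np.where(bio7 > 0, 100.0 * bio2 / np.where(bio7 > 0, bio7, 1.0), np.nan)
    bio3_mask = mask | ~np.isfinite(bio3)
    bio3 = np.nan_to_num(bio3, nan=0.0)

    quarters = _quarters(climate.months)
    if not quarters:
        raise InsufficientMonthsError("no run of 3 consecutive months available")
    qmeans = np.stack([np.mean([means[m] for m in q], axis=0) for q in quarters])
    warmest = qmeans.max(axis=0)
    coldest = qmeans.min(axis=0)

    values = {
        "BIO1": bio1, "BIO2": bio2, "BIO3": bio3, "BIO4": bio4, "BIO5": bio5,
        "BIO6": bio6, "BIO7": bio7, "BIO8": warmest, "BIO9": coldest,
        "BIO10": warmest.copy(), "BIO11": coldest.copy(),
    }
    variables = {
        code: ref.like(values[code], bio3_mask.copy() if code == "BIO3" else mask.copy())
        for code in BIOCLIM_CODES
    }
    label = period_label if period_label is not None else climate.period_label
    return BioclimStack(variables, tuple(climate.months), label)


def seasonal_average(climate: MonthlyClimate, season: str) -> SeasonalMeans:
    """Cellwise mean tmin/tmax/tmean over the fixed three-month season."""
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; expected one of {list(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    missing = [m for m in months if m not in climate.months]
    if missing:
        raise InsufficientMonthsError(f"season {season!r} needs months {missing}")
    ref = climate.grid
    grids = [climate.tmin[m] for m in months] + [climate.tmax[m] for m in months]
    mask = combined_mask(*grids)
    tmin = np.mean([climate.tmin[m].values for m in months], axis=0)
    tmax = np.mean([climate.tmax[m].values for m in months], axis=0)
    return SeasonalMeans(
        season,
        ref.like(tmin, mask.copy()),
        ref.like(tmax, mask.copy()),
        ref.like((tmin + tmax) / 2.0, mask.copy()),
    )
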