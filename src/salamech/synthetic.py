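"""Synthetic mountain landscapes, microclimate, humidity and occurrences.

Every downstream stage of the pipeline (bioclim derivation, SDM fitting,
metabolic/moisture mapping, agreement, corridors) is exercised on data from
this module, so nothing requires a download.  The generator emulates the
statistical structure the analysis assumes:

* a smooth, spatially correlated elevation field spanning a mountainous
  range (265-2025 m by default);
* lapse-rate-driven monthly maximum temperature with a seasonal harmonic,
  a smooth mesoscale anomaly, and fine-scale microclimate noise with a
  short correlation length (the feature that makes correlative and
  mechanistic surfaces diverge at native resolution);
* additive warming offsets standing in for downscaled emission-scenario
  projections;
* a seasonal specific-humidity cycle;
* occurrences sampled from a known high-elevation suitability function,
  giving a ground truth for recovery tests.

All outputs are pure functions of :class:`ScenarioConfig`, including its
seed: the same config always yields bit-identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import InvalidConfigError, NoValidCellsError
from .raster import RasterGrid, require_same_grid

GROWING_SEASON_MONTHS = tuple(range(3, 12))  # March-November


@dataclass
class MonthlyClimate:
    """Per-month minimum/maximum near-surface temperature stacks (deg C)."""

    months: tuple[int, ...]
    tmin: dict[int, RasterGrid]
    tmax: dict[int, RasterGrid]
    period_label: str = "2010"

    def __post_init__(self):
        self.months = tuple(self.months)
        grids = [self.tmin[m] for m in self.months] + [self.tmax[m] for m in self.months]
        require_same_grid(*grids)
        for m in self.months:
            lo, hi = self.tmin[m], self.tmax[m]
            ok = lo.valid & hi.valid
            if np.any(lo.values[ok] > hi.values[ok] + 1e-9):
                raise InvalidConfigError(f"month {m}: tmin exceeds tmax")

    @property
    def grid(self) -> RasterGrid:
        return self.tmax[self.months[0]]

    def tmean(self, month: int) -> RasterGrid:
        lo, hi = self.tmin[month], self.tmax[month]
        return lo.like((lo.values + hi.values) / 2.0, lo.nodata_mask | hi.nodata_mask)


@dataclass
class OccurrenceSet:
    """Deduplicated species occurrence points in map coordinates."""

    points: np.ndarray  # (n, 2) of x, y
    species: str = "synthetic"

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 2)

    @property
    def n_unique(self) -> int:
        return len(np.unique(self.points, axis=0))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study landscape.

    Temperature model, per month ``m`` and cell::

        tmax = tmax_ref + seasonal_amp * cos(2*pi*(m - month_peak)/12)
               - lapse_rate * elevation
               + mesoscale_amp * meso + micro_amp * micro_m
        tmin = tmax - diurnal_range - tmin_noise_amp * |noise_m|

    ``meso`` is one smooth long-range field shared by all months; ``micro_m``
    is an independent short-correlation-length field per month - the
    fine-scale microclimate texture.  Units: temperatures in deg C, lapse in
    deg C per meter, humidity in kg/kg, lengths in cells unless noted.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 3.0
    elevation_range: tuple[float, float] = (265.0, 2025.0)
    elevation_corr_len: float = 18.0  # cells; mountain-scale smoothness
    hypsometry: str = "equalized"  # rank-equalized to a fixed hypsometric curve; or "minmax"
    hypsometry_exponent: float = 2.0  # >1 = bottom-heavy (summit area is scarce)
    ridge_rough_amp: float = 0.6  # summit dissection, in SDs of the base field
    ridge_rough_corr_len: float = 8.0  # cells
    ridge_rough_exponent: float = 3.0  # how sharply dissection concentrates at summits
    lapse_rate: float = 0.006
    tmax_ref: float = 28.0  # sea-level tmax at the seasonal peak month
    seasonal_amp: float = 9.0
    seasonal_amp_lapse: float = 0.0005  # deg C of amplitude lost per m
    month_peak: int = 7
    diurnal_range: float = 8.0
    diurnal_range_lapse: float = 0.0008  # deg C of diurnal range lost per m
    mesoscale_amp: float = 1.0
    mesoscale_corr_len: float = 40.0
    micro_amp: float = 1.0
    micro_corr_len: float = 5.0
    tmin_noise_amp: float = 0.3
    months: tuple[int, ...] = GROWING_SEASON_MONTHS
    warming_offsets: dict = field(default_factory=lambda: {"2010": 0.0, "2030": 1.1, "2050": 2.0})
    humidity_mean: float = 0.0075  # kg/kg
    humidity_amp: float = 0.0045
    n_year_average: int = 1  # >1 averages independent yearly draws
    seed: int = 0

    def monthly_humidity(self) -> dict[int, float]:
        """Seasonal specific-humidity cycle (kg/kg), peaking at month_peak."""
        return {
            m: self.humidity_mean
            + self.humidity_amp * math.cos(2.0 * math.pi * (m - self.month_peak) / 12.0)
            for m in self.months
        }

    def validate(self) -> None:
        nr, nc = self.shape
        if nr < 16 or nc < 16:
            raise InvalidConfigError("grid shape must be at least 16x16")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        lo, hi = self.elevation_range
        if hi < lo:
            raise InvalidConfigError("elevation_range must be (low, high)")
        if self.diurnal_range < 0:
            raise InvalidConfigError("diurnal_range must be non-negative")
        if self.hypsometry not in ("equalized", "minmax"):
            raise InvalidConfigError("hypsometry must be 'equalized' or 'minmax'")
        if self.hypsometry_exponent <= 0:
            raise InvalidConfigError("hypsometry_exponent must be positive")
        if self.ridge_rough_amp < 0:
            raise InvalidConfigError("ridge_rough_amp must be >= 0")
        _, top = self.elevation_range
        if self.diurnal_range - self.diurnal_range_lapse * top < 0:
            raise InvalidConfigError("diurnal range goes negative at the summit")
        if self.seasonal_amp - self.seasonal_amp_lapse * top < 0:
            raise InvalidConfigError("seasonal amplitude goes negative at the summit")
        if self.n_year_average < 1:
            raise InvalidConfigError("n_year_average must be >= 1")


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def _smooth_field(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with the given correlation
    length (cells), built by smoothing white noise."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    f = gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_elevation(config: ScenarioConfig) -> RasterGrid:
    """Smooth elevation field rescaled to the configured range.

    The min/max of the output hit the configured endpoints exactly; with a
    degenerate range (low == high) the raster is constant.  With the
    default ``hypsometry='equalized'`` the smooth field is rank-equalized to
    a fixed hypsometric curve, elevation = lo + (hi-lo) * u**a with u the
    areal rank and ``a = hypsometry_exponent``: spatial arrangement varies
    with the seed but the area fraction above any elevation does not, and
    a > 1 makes summit area scarce the way real mountain hypsometry is.
    ``hypsometry='minmax'`` is the plain affine rescale.  A fine-scale
    roughness term weighted toward the summits (``ridge_rough_*``) dissects
    the high ground into separate knobs, as real ridge systems are.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    f = _smooth_field(config.shape, config.elevation_corr_len, rng)
    if config.ridge_rough_amp > 0:
        # fine-scale dissection that grows toward the summits, emulating the
        # rugged upper slopes of real mountain terrain
        rough = _smooth_field(config.shape, config.ridge_rough_corr_len,
                              _rng(config.seed, 9))
        order = np.argsort(f, axis=None, kind="stable")
        u = np.empty(f.size)
        u[order] = np.arange(f.size) / max(f.size - 1, 1)
        weight = u.reshape(f.shape) ** config.ridge_rough_exponent
        f = f + config.ridge_rough_amp * weight * rough
    lo, hi = config.elevation_range
    fmin, fmax = f.min(), f.max()
    if hi == lo or fmax == fmin:
        vals = np.full(config.shape, float(lo))
    elif config.hypsometry == "equalized":
        order = np.argsort(f, axis=None, kind="stable")
        u = np.empty(f.size)
        u[order] = np.arange(f.size) / (f.size - 1)
        vals = lo + u.reshape(f.shape) ** config.hypsometry_exponent * (hi - lo)
    else:
        vals = lo + (f - fmin) * (hi - lo) / (fmax - fmin)
    return RasterGrid(vals, config.cell_size)


def generate_monthly_temperature(elevation: RasterGrid, config: ScenarioConfig,
                                 period_label: str = "2010") -> MonthlyClimate:
    """Monthly tmin/tmax stacks over the given elevation field.

    With all noise amplitudes zero the mean temperature is an exact linear
    function of elevation (strictly decreasing for a positive lapse rate).
    Multi-year averaging (``n_year_average``) draws independent noise per
    year and averages, which damps the microclimate texture the way a
    multi-year period mean would.
    """
    config.validate()
    elev = elevation.values
    tmins: dict[int, RasterGrid] = {}
    tmaxs: dict[int, RasterGrid] = {}
    meso = _smooth_field(config.shape, config.mesoscale_corr_len, _rng(config.seed, 2))
    for m in config.months:
        tmax_acc = np.zeros(config.shape)
        tnoise_acc = np.zeros(config.shape)
        for year in range(config.n_year_average):
            micro = _smooth_field(config.shape, config.micro_corr_len,
                                  _rng(config.seed, 3, m, year))
            noise = _smooth_field(config.shape, config.micro_corr_len,
                                  _rng(config.seed, 4, m, year))
            tmax_acc += config.micro_amp * micro
            tnoise_acc += config.tmin_noise_amp * np.abs(noise)
        amp = config.seasonal_amp - config.seasonal_amp_lapse * elev
        harmonic = amp * math.cos(2.0 * math.pi * (m - config.month_peak) / 12.0)
        tmax = (
            config.tmax_ref
            + harmonic
            - config.lapse_rate * elev
            + config.mesoscale_amp * meso
            + tmax_acc / config.n_year_average
        )
        drange = config.diurnal_range - config.diurnal_range_lapse * elev
        tmin = tmax - drange - tnoise_acc / config.n_year_average
        tmaxs[m] = elevation.like(tmax)
        tmins[m] = elevation.like(tmin)
    return MonthlyClimate(config.months, tmins, tmaxs, period_label)


def apply_warming(climate: MonthlyClimate, offset_c: float,
                  period_label: str | None = None) -> MonthlyClimate:
    """Uniform additive warming; geometry and month set unchanged."""
    if not np.isfinite(offset_c):
        raise InvalidConfigError("warming offset must be finite")
    label = period_label if period_label is not None else climate.period_label
    tmins = {m: g.like(g.values + offset_c) for m, g in climate.tmin.items()}
    tmaxs = {m: g.like(g.values + offset_c) for m, g in climate.tmax.items()}
    return MonthlyClimate(climate.months, tmins, tmaxs, label)


def true_suitability(elevation: RasterGrid, midpoint: float = 1100.0,
                     steepness: float = 0.008) -> RasterGrid:
    """Known ground-truth suitability: logistic in elevation.

    Values lie in [0, 1], equal 0.5 at the midpoint elevation, and are
    monotone non-decreasing in elevation for positive steepness - the
    high-elevation-specialist assumption.
    """
    if not (np.isfinite(midpoint) and np.isfinite(steepness)):
        raise InvalidConfigError("logistic parameters must be finite")
    vals = expit(steepness * (elevation.values - midpoint))
    return elevation.like(vals)


def sample_occurrences(suitability: RasterGrid, n: int, seed: int,
                       species: str = "synthetic", jitter: bool = True) -> OccurrenceSet:
    """Sample presence points with probability proportional to suitability.

    Cells are drawn (with replacement) proportionally to their suitability;
    each point is then jittered uniformly within its cell and exact
    duplicates are removed.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    weights = np.where(suitability.valid, np.clip(suitability.values, 0.0, None), 0.0)
    total = weights.sum()
    if total <= 0:
        raise NoValidCellsError("suitability has no positive non-nodata cells")
    rng = _rng(seed, 11)
    flat = weights.ravel() / total
    idx = rng.choice(flat.size, size=n, replace=True, p=flat)
    rows, cols = np.unravel_index(idx, suitability.shape)
    x, y = suitability.cell_center(rows, cols)
    if jitter:
        cs = suitability.cell_size
        x = x + rng.uniform(-0.5, 0.5, size=n) * cs
        y = y + rng.uniform(-0.5, 0.5, size=n) * cs
    pts = np.unique(np.column_stack([x, y]), axis=0)
    return OccurrenceSet(pts, species)


def sample_background(grid: RasterGrid, n: int, seed: int,
                      species: str = "background") -> OccurrenceSet:
    """Uniform background points over the non-nodata extent (with jitter)."""
    uniform = grid.like(np.ones(grid.shape))
    uniform.nodata_mask = grid.nodata_mask.copy()
    return sample_occurrences(uniform, n, seed + 7919, species)
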