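"""Vapor pressure deficit (VPD) from minimum temperature and humidity.

VPD is the gap between saturation vapor pressure at air temperature and the
actual vapor pressure of the air; high VPD dries a lungless salamander's
skin and suppresses surface activity.  Because the animals are mostly
night-active, the deficit is computed from *minimum* (nocturnal proxy)
temperatures.

Saturation vapor pressure uses the Tetens form by default,

    es(T) = 0.6108 * exp(17.27 * T / (T + 237.3))   [kPa, T in deg C]

(the Magnus constants are available as an alternate dialect); actual vapor
pressure converts specific humidity q (kg/kg) at air pressure P (kPa) via

    ea = q * P / (0.622 + 0.378 * q).

Pressure defaults to the standard barometric formula on the elevation
raster.  VPD is clipped at zero: saturated or supersaturated air has no
deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PhysiologyDomainError
from .raster import RasterGrid, require_same_grid
from .synthetic import MonthlyClimate
from .bioclim import SEASON_MONTHS

TETENS = (0.6108, 17.27, 237.3)
MAGNUS = (0.61094, 17.625, 243.04)

STANDARD_PRESSURE_KPA = 101.325


@dataclass
class HumidityInput:
    """Specific humidity plus the air pressure needed to convert it.

    ``q`` may be a scalar (kg/kg, spatially uniform for the month) or a
    RasterGrid; ``pressure_kpa`` likewise, and defaults to the barometric
    profile of the supplied elevation raster.
    """

    q: float | RasterGrid
    pressure_kpa: float | RasterGrid | None = None
    elevation: RasterGrid | None = None

    def resolve_pressure(self, grid: RasterGrid) -> np.ndarray:
        if self.pressure_kpa is not None:
            if isinstance(self.pressure_kpa, RasterGrid):
                require_same_grid(grid, self.pressure_kpa)
                return self.pressure_kpa.values
            return np.full(grid.shape, float(self.pressure_kpa))
        if self.elevation is not None:
            require_same_grid(grid, self.elevation)
            return barometric_pressure(self.elevation.values)
        return np.full(grid.shape, STANDARD_PRESSURE_KPA)

    def resolve_q(self, grid: RasterGrid) -> np.ndarray:
        if isinstance(self.q, RasterGrid):
            require_same_grid(grid, self.q)
            qv = self.q.values
        else:
            qv = np.full(grid.shape, float(self.q))
        if np.any(qv < 0) or np.any(qv >= 0.1):
            raise PhysiologyDomainError("specific humidity must satisfy 0 <= q < 0.1 kg/kg")
        return qv


@dataclass
class VpdSurface:
    """Minimum vapor pressure deficit raster (kPa)."""

    vpd: RasterGrid
    season: str = "summer"
    period_label: str = "2010"
    humidity_source: str = "synthetic"


def barometric_pressure(elevation_m) -> np.ndarray:
    """Standard-atmosphere pressure (kPa) at the given elevation (m)."""
    z = np.asarray(elevation_m, float)
    return STANDARD_PRESSURE_KPA * np.power(1.0 - 2.25577e-5 * z, 5.25588)


def saturation_vapor_pressure(t_c, constants=TETENS):
    """Saturation vapor pressure es (kPa) at air temperature t_c (deg C)."""
    a, b, c = constants
    t = np.asarray(t_c, float)
    if np.any(t <= -c):
        raise PhysiologyDomainError(f"temperature must exceed {-c} deg C")
    out = a * np.exp(b * t / (t + c))
    return out if out.ndim else float(out)


def actual_vapor_pressure(q, pressure_kpa):
    """Actual vapor pressure ea (kPa) from specific humidity and pressure."""
    qv = np.asarray(q, float)
    pv = np.asarray(pressure_kpa, float)
    out = qv * pv / (0.622 + 0.378 * qv)
    return out if out.ndim else float(out)


def compute_min_vpd(tmin: RasterGrid, humidity: HumidityInput,
                    season: str = "summer", period_label: str = "2010",
                    constants=TETENS) -> VpdSurface:
    """vpd = max(es(tmin) - ea, 0) on the tmin grid."""
    qv = humidity.resolve_q(tmin)
    pv = humidity.resolve_pressure(tmin)
    es = saturation_vapor_pressure(tmin.values, constants)
    ea = actual_vapor_pressure(qv, pv)
    vpd = np.clip(es - ea, 0.0, None)
    src = "raster q" if isinstance(humidity.q, RasterGrid) else f"q={humidity.q:g} kg/kg"
    return VpdSurface(tmin.like(vpd), season, period_label, src)


def seasonal_min_vpd(climate: MonthlyClimate, humidity_by_month: dict[int, float],
                     season: str, elevation: RasterGrid | None = None,
                     constants=TETENS) -> VpdSurface:
    """Monthly minimum VPD averaged over a season's months.

    Computed month-by-month from monthly tmin and monthly specific humidity,
    then averaged - matching the monthly granularity of the inputs.
    """
    months = SEASON_MONTHS[season]
    monthly = []
    mask = None
    ref = climate.grid
    for m in months:
        hum = HumidityInput(humidity_by_month[m], elevation=elevation)
        surf = compute_min_vpd(climate.tmin[m], hum, season, climate.period_label, constants)
        monthly.append(surf.vpd.values)
        mask = surf.vpd.nodata_mask if mask is None else (mask | surf.vpd.nodata_mask)
    mean = np.mean(monthly, axis=0)
    return VpdSurface(ref.like(mean, mask), season, climate.period_label, "monthly q table")
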