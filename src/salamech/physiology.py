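"""Body-mass clines and standard metabolic rate (SMR) mapping.

Salamander body mass is modelled as a species-specific linear function of
elevation (ordinary least squares on field samples), and standard metabolic
rate as a log-linear function of temperature and body mass, the regression
form used for temperate plethodontids:

    log10(VO2) = b0 + b1 * log10(M) + b2 * T

with VO2 in uL O2 g^-1 h^-1 (mass-specific basis, ``b1`` typically negative)
or uL O2 h^-1 (whole-animal basis, ``b1`` typically ~0.7-0.9).  ``b2 > 0``:
metabolic cost rises with temperature.  The default coefficients shipped in
:data:`DEFAULT_SPECIES` are plausible synthetic fixtures of this form, not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import PhysiologyDomainError, SingularFitError
from .raster import RasterGrid, combined_mask, require_same_grid

MASS_FLOOR_G = 0.1  # prevents log10 domain errors at extrapolated low elevations


@dataclass
class MassElevationModel:
    """OLS fit of body mass (g) on elevation (m)."""

    intercept: float  # g
    slope: float  # g per m
    residual_sd: float  # g
    r_squared: float
    species: str = "synthetic"


@dataclass
class SmrCoefficients:
    """Coefficients of the log-linear SMR regression."""

    b0: float
    b1: float
    b2: float  # per deg C, > 0
    output_basis: str = "per-gram"  # or "whole-animal"

    def __post_init__(self):
        if self.b2 <= 0:
            raise PhysiologyDomainError("b2 must be > 0 (SMR increases with temperature)")
        if self.output_basis not in ("per-gram", "whole-animal"):
            raise ValueError("output_basis must be 'per-gram' or 'whole-animal'")


@dataclass
class SpeciesParams:
    """Species-level configuration: mass cline, SMR coefficients, range."""

    label: str
    mass_intercept: float  # g at 0 m
    mass_slope: float  # g per m
    mass_residual_sd: float  # g
    smr: SmrCoefficients
    elevation_range: tuple[float, float] = (665.0, 2025.0)


@dataclass
class SmrSurface:
    """Mapped standard metabolic rate (VO2, uL g^-1 h^-1 by default)."""

    vo2: RasterGrid
    species: str = "synthetic"
    season: str = "summer"
    period_label: str = "2010"


# Synthetic fixture coefficients with realistic form and signs: a small
# high-elevation species and a larger one, both mass-specific SMR.
DEFAULT_SPECIES = {
    "small-bodied": SpeciesParams(
        label="small-bodied",
        mass_intercept=0.25, mass_slope=2.0e-4, mass_residual_sd=0.08,
        smr=SmrCoefficients(b0=-0.10, b1=-0.25, b2=0.035),
    ),
    "large-bodied": SpeciesParams(
        label="large-bodied",
        mass_intercept=1.50, mass_slope=1.2e-3, mass_residual_sd=0.50,
        smr=SmrCoefficients(b0=-0.05, b1=-0.25, b2=0.032),
    ),
}


def fit_mass_elevation(samples, species: str = "synthetic") -> MassElevationModel:
    """OLS fit of mass on elevation from (elevation_m, mass_g) pairs."""
    arr = np.asarray(samples, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (elevation, mass) samples")
    elev, mass = arr[:, 0], arr[:, 1]
    if np.ptp(elev) == 0:
        raise SingularFitError("elevations are all equal; slope is unidentifiable")
    res = stats.linregress(elev, mass)
    resid = mass - (res.intercept + res.slope * elev)
    dof = max(len(arr) - 2, 1)
    return MassElevationModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        r_squared=float(res.rvalue**2),
        species=species,
    )


def simulate_mass_samples(params: SpeciesParams, n: int, seed: int) -> np.ndarray:
    """Draw synthetic (elevation, mass) field samples from a species' cline."""
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 21])
    lo, hi = params.elevation_range
    elev = rng.uniform(lo, hi, size=n)
    mass = params.mass_intercept + params.mass_slope * elev
    mass = mass + rng.normal(0.0, params.mass_residual_sd, size=n)
    return np.column_stack([elev, np.clip(mass, MASS_FLOOR_G, None)])


def predict_mass(elevation: RasterGrid, model: MassElevationModel,
                 floor_g: float = MASS_FLOOR_G) -> RasterGrid:
    """Mass raster a0 + a1*elevation, clamped below at the mass floor."""
    vals = model.intercept + model.slope * elevation.values
    return elevation.like(np.clip(vals, floor_g, None))


def compute_smr(temperature: RasterGrid, mass: RasterGrid, coef: SmrCoefficients,
                species: str = "synthetic", season: str = "summer",
                period_label: str = "2010") -> SmrSurface:
    """Map VO2 = 10^(b0 + b1*log10(M) + b2*T) over aligned rasters.

    Strictly increasing in temperature; monotone in mass with the sign of
    ``b1``.  Raises on any non-positive mass cell.
    """
    require_same_grid(temperature, mass)
    mask = combined_mask(temperature, mass)
    m = mass.values
    if np.any(m[~mask] <= 0):
        raise PhysiologyDomainError("mass must be positive at every data cell")
    safe_m = np.where(mask, 1.0, m)
    log10_vo2 = coef.b0 + coef.b1 * np.log10(safe_m) + coef.b2 * temperature.values
    vo2 = np.power(10.0, log10_vo2)
    return SmrSurface(temperature.like(vo2, mask), species, season, period_label)
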