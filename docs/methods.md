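# Methods

## The two model families and what is compared

The package builds two maps of the same thing — where a terrestrial
salamander can afford to be — from the same monthly microclimate inputs,
then quantifies how much they agree.

**Correlative side.** Habitat suitability `p(x) ∈ [0, 1]` is fitted to
occurrence points against background points using temperature bioclim
predictors (BIO1–BIO11).  Two simple learners fill the ensemble: a
percentile climate envelope (score 1 inside the 5–95% presence interval of
each variable, linear decay to 0 at the presence min/max extended by one
interquartile range, min across variables) and an L2-penalized logistic
regression on standardized predictors.  The logistic penalty is scaled as
mean log-loss + (λ/2)‖w‖², so uniformly duplicating the training rows does
not move the fit; inside the ensemble the two classes receive equal total
weight (the prevalence-0.5 output convention of standard
presence-background suitability software), so a 10:1 background ratio does
not depress the probabilities.  Members are combined by a weighted mean
with weights max(AUC_cv − 0.5, 0), and cells with `p ≥ 0.7` are "highly
suitable".  Evaluation uses AUC (Mann–Whitney form), maximum TSS over a
0.01 threshold grid, and the Continuous Boyce Index with 100 moving
windows of width range/10 (Spearman correlation of window center vs. the
presence-to-expected ratio; zero-expectation windows dropped).

**Mechanistic side.** Standard metabolic rate is mapped as
`log10 VO2 = b0 + b1·log10 M + b2·T` with body mass `M` predicted from a
species-specific OLS cline on elevation (clamped at 0.1 g so the log is
defined under extrapolation).  The shipped coefficients are synthetic
fixtures of realistic form and sign (mass-specific basis, `b1 < 0`,
`b2 ≈ 0.032–0.035 /°C`, i.e. Q10 ≈ 2); whole-animal basis is a config
switch.  Minimum vapor pressure deficit uses the Tetens saturation curve
`es = 0.6108·exp(17.27 T/(T+237.3))` kPa on monthly minimum temperature
(the animals are night-active), actual vapor pressure
`ea = q·P/(0.622+0.378q)` from specific humidity, and barometric pressure
evaluated on the elevation raster; `vpd = max(es − ea, 0)` is computed
monthly and then season-averaged (computing on seasonal mean temperatures
instead is a config switch).  Per season and period, SMR and VPD are
min–max rescaled to [0, 1] over the full study mask, summed with equal
weight and multiplied by 100: a 0–200 resistance-to-surface-activity
raster.  Rescaling makes resistance invariant to positive affine
transforms of either raw layer — and makes it a *relative* quantity within
each season/period, which is why warming-direction checks run on the raw
layers.  High-priority areas are cells with SMR ≤ median and VPD ≤ median,
medians taken inside the species' elevational range (665–2025 m default),
per season, with a cross-season intersection/union report.

**Agreement.** Spearman's ρ between suitability and resistance values
extracted at random sample points (distinct cells, without replacement);
negative ρ means agreement because good conditions are high-`p` but
low-resistance.  The multi-resolution curve aggregates both rasters by
block means over a strictly increasing ladder of cell sizes, maps the one
reused point set to coarse cells, drops duplicate cells, and recomputes ρ;
`convergence_resolution` returns the smallest resolution after which |ρ|
changes by less than ε = 0.01 for two consecutive steps.  Block means use
the center-in-cell rule (a fine cell belongs to the coarse cell containing
its center); exact area weighting is available as `method="area"`.

**Connectivity and fragmentation.** Core areas are 8-connected components
of the highly suitable mask above a minimum area (cell threshold
`ceil(min_area·10⁶ / cell_area)`).  Least-cost paths are computed by a
multi-source Dijkstra: all source-patch cells start at zero cost, a step
between neighbors costs the mean of the two resistances times the
center-to-center distance (×√2 diagonally), nodata cells are barriers, and
ties break deterministically (lexicographic neighbor order N, NE, E, SE,
S, SW, W, NW with stable queue insertion).  Paths are buffered by a
Euclidean cell-center distance to form corridors; habitat is clipped to
the corridor mask and summarized by mean Euclidean nearest-neighbor
distance between patch boundary cells (FRAGSTATS convention), patch
density per hectare of corridor (denominator configurable), and mean
perimeter/area with perimeter counted as exposed cell faces.

## The synthetic landscape: what it emulates, and what it does not

The generator is the package's study system.  Elevation is a smoothed
Gaussian field rank-equalized to a fixed hypsometric curve
`z = lo + (hi−lo)·u^a` with `a = 2`: summit area is scarce the way real
mountain hypsometry is, and the area above any elevation is identical
across seeds (only the spatial arrangement varies), which keeps habitat
fractions comparable between runs.  A fine-scale roughness term whose
amplitude grows toward the summits (`ridge_rough_*`) dissects the high
ground into separate knobs — the structural reason warming pushes habitat
into intrinsically more fragmented terrain.  Monthly maximum temperature
is `tmax_ref + A(z)·cos(2π(m−m_peak)/12) − lapse·z + mesoscale +
fine-scale noise`, with mild elevational clines on the seasonal amplitude
and the diurnal range so that *all* eleven bioclims carry elevation signal
(with constant diurnal range, BIO2/BIO3/BIO4/BIO7 would be pure noise and
would randomly degrade any envelope-style learner — unrealistically so).
The fine-scale field (correlation length 5 cells, amplitude 1 °C) is the
knob that makes the correlative and mechanistic surfaces diverge at native
resolution and re-converge under aggregation.  Future periods are uniform
additive offsets (+1.1 °C, +2 °C) with specific humidity held at the
baseline seasonal cycle.  The known truth is a logistic in elevation
(midpoint 1500 m, steepness 0.02 /m — graded enough that the truth has no
rank ties, concentrated enough that occurrences are genuinely
high-elevation), and presences are drawn proportional to it, jittered
within cells, deduplicated.

What the generator does **not** emulate: real topography and its
anisotropy, vegetation and canopy buffering, spatially heterogeneous
climate-change deltas (warming here is exactly uniform), humidity
downscaling, multi-year weather variability (a period is one
representative year unless `n_year_average > 1`), and observation biases
in occurrence records.  Passing tests therefore show that the pipeline's
machinery reproduces the qualitative spatio-temporal structure — weak
fine-scale agreement that strengthens and plateaus under coarsening,
attenuated agreement inside suitable habitat, warming-driven habitat loss,
corridor lengthening and habitat shredding — under controlled conditions,
not that any particular field system behaves this way.

## The standard scenario and problem sizes

Unit tests run on 16–100-cell-wide grids.  The standard comparison study
(`standard_config`) is a 400×400 grid at 3 m (1.2 × 1.2 km), 500
presences, 5 000 background points, up to 100 000 agreement sample points,
resolutions 3–96 m, a 0.004 km² core-area minimum and a 30 m corridor
buffer, with baseline and +2 °C periods.  The core-area minimum and buffer
radius are scaled to the desk-scale extent deliberately: at the canonical
1 km² / 300 m values a 1.2 km domain holds at most one core and the
"corridor" covers half the landscape, so the corridor statistics would
measure geometry of the buffer, not of the habitat network.  The bundled
smoke scenario (64×64 at 30 m) exists for end-to-end and reproducibility
checks, not for inference.

Desk-scale corridor statistics remain the noisiest part of the pipeline:
with ~10 cores per period, which particular cores survive warming moves
the complete-graph mean path length and the corridor-clipped patch density
by tens of percent between seeds, even though the underlying signals —
habitat loss, longer paths between surviving cores, smaller within-corridor
patches — are stable.  The mean patch area within corridors (a
denominator-free shredding measure) decreases under warming in every seed
we examined and is reported alongside PD by the acceptance script.

## Numerical and convention choices

* Rasters are planar, meter-unit, row 0 = north, half-open cells; GeoTIFF
  I/O is via tifffile with ModelPixelScale/ModelTiepoint/GeoKeyDirectory
  tags, and geographic-CRS rasters are rejected.
* BIO4 uses the population SD (×100), the dominant bioclim convention
  (sample SD is a switch); quarters are any three consecutive months
  within March–November, no wraparound; with no precipitation layers BIO8
  and BIO9 coincide with BIO10 and BIO11 by construction.
* `rescale01` maps a constant layer to all zeros (lowest resistance).
* Thresholds are inclusive (`p ≥ 0.7`); the TSS default threshold
  maximizes TSS on a 0.01 grid.
* k = 5 cross-validation folds by default; partitions are deterministic
  per seed.
* Logistic fits stop at tolerance 1e-8 or 500 iterations; with λ = 0 and
  separable classes the unbounded-likelihood condition (a fitted direction
  that fully separates the classes) raises an error advising λ > 0.
* Dijkstra returns the first-settled target cell; equal-cost paths resolve
  by the fixed neighbor order, so reruns are bit-identical.
* ENN uses boundary-cell center-to-center distances and population SD;
  with fewer than two patches it is reported as NaN (missing), matching
  landscape-metric conventions.
* All randomness flows through named integer seeds; every artifact file is
  checksummed in the run manifest.

## Known limitations

The ensemble holds two in-repo learners, not the wider algorithm zoos used
in production SDM work; the resistance model is the plain equal-weight
sum of two rescaled layers (no acclimation, plasticity, or
evaporative-water-loss biophysics); corridors are optimal single paths,
not current-flow or corridor-width models; and the exact species
coefficients (mass clines, metabolic regressions) are configuration, to be
replaced with measured values for any real application.
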