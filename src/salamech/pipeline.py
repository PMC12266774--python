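"""Scenario driver: configuration, orchestration, artifacts, manifest.

``run_scenario`` chains every stage for each species x season x period:
synthetic landscape -> bioclim -> SDM ensemble (fit on the baseline period,
projected onto each period's bioclims) -> SMR / VPD / resistance -> HPA ->
agreement tables and resolution curves -> core areas, least-cost corridors
-> fragmentation metrics.  Every output file is listed in a manifest with a
content checksum, and all randomness flows through named seeds recorded in
the manifest, so deterministic artifacts reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import bioclim as bc
from . import connectivity as conn
from . import fragmentation as frag
from . import moisture as moist
from . import physiology as phys
from . import resistance as resist
from . import sdm
from . import synthetic as syn
from .errors import InvalidConfigError
from .raster import RasterGrid, write_raster

log = logging.getLogger("salamech")

SEASONS = ("spring", "summer", "fall")


@dataclass
class StudyConfig:
    """Full configuration of a synthetic comparison study."""

    scenario: syn.ScenarioConfig = field(default_factory=syn.ScenarioConfig)
    species: list[phys.SpeciesParams] = field(
        default_factory=lambda: [phys.DEFAULT_SPECIES["small-bodied"]])
    suitability_midpoint: float = 1500.0
    suitability_steepness: float = 0.02
    n_presences: int = 300
    background_ratio: float = 10.0
    mass_sample_n: int = 100
    sdm_l2: float = 0.01
    sdm_pct: tuple[float, float] = (5.0, 95.0)
    sdm_cutoff: float = 0.7
    sdm_k: int = 5
    sdm_weighting: str = "auc"
    agreement_n_points: int = 100_000
    resolutions: list[float] | None = None
    min_core_area_km2: float = 1.0
    buffer_radius_m: float = 300.0
    connectivity: int = 8
    seasons: tuple[str, ...] = SEASONS
    seed: int = 0

    def periods(self) -> list[str]:
        offs = self.scenario.warming_offsets
        return sorted(offs, key=lambda k: (offs[k], k))

    def baseline_period(self) -> str:
        return self.periods()[0]

    def resolution_ladder(self, grid: RasterGrid) -> list[float]:
        if self.resolutions:
            return list(self.resolutions)
        extent = min(grid.shape) * grid.cell_size
        return agr.default_resolution_ladder(grid.cell_size, extent)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["shape"] = list(self.scenario.shape)
        d["scenario"]["elevation_range"] = list(self.scenario.elevation_range)
        d["scenario"]["months"] = list(self.scenario.months)
        d["sdm_pct"] = list(self.sdm_pct)
        d["seasons"] = list(self.seasons)
        for sp in d["species"]:
            sp["elevation_range"] = list(sp["elevation_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        try:
            sc = dict(d.pop("scenario", {}))
            for key in ("shape", "elevation_range", "months"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            species = []
            for sp in d.pop("species", []):
                sp = dict(sp)
                smr = phys.SmrCoefficients(**sp.pop("smr"))
                sp["elevation_range"] = tuple(sp.get("elevation_range", (665.0, 2025.0)))
                species.append(phys.SpeciesParams(smr=smr, **sp))
            cfg = cls(scenario=syn.ScenarioConfig(**sc), **d)
        except TypeError as exc:
            raise InvalidConfigError(f"bad config field: {exc}") from exc
        if species:
            cfg.species = species
        cfg.sdm_pct = tuple(cfg.sdm_pct)
        cfg.seasons = tuple(cfg.seasons)
        cfg.scenario.validate()
        if not 0.0 <= cfg.sdm_cutoff <= 1.0:
            raise InvalidConfigError("sdm_cutoff must lie in [0, 1]")
        if cfg.buffer_radius_m < 0:
            raise InvalidConfigError("buffer_radius_m must be >= 0")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def smoke_config() -> StudyConfig:
    """The bundled desk-scale smoke scenario (64x64 grid, 2 periods)."""
    from importlib.resources import files

    return StudyConfig.from_yaml(files("salamech").joinpath("data/smoke.yaml"))


def standard_config(seed: int = 0) -> StudyConfig:
    """The standard synthetic comparison scenario.

    A 400 x 400 grid at 3 m (1.2 km x 1.2 km) with baseline and +2 deg C
    periods; core-area and sampling thresholds are scaled to the desk-scale
    extent (the study system's park-scale extent is not reproduced).
    """
    scenario = syn.ScenarioConfig(
        shape=(400, 400),
        warming_offsets={"2010": 0.0, "2050": 2.0},
        seed=seed,
    )
    return StudyConfig(
        scenario=scenario,
        n_presences=500,
        agreement_n_points=100_000,
        resolutions=[3.0, 6.0, 12.0, 24.0, 48.0, 96.0],
        min_core_area_km2=0.004,
        buffer_radius_m=30.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Study assembly (in-memory)
# ---------------------------------------------------------------------------


@dataclass
class SpeciesStudy:
    params: phys.SpeciesParams
    truth: RasterGrid
    occurrences: syn.OccurrenceSet
    background: syn.OccurrenceSet
    mass_model: phys.MassElevationModel
    mass: RasterGrid
    surfaces: dict[str, sdm.SuitabilitySurface]  # period -> ensemble surface
    suitable: dict[str, RasterGrid]  # period -> boolean mask
    reports: dict[str, sdm.EvaluationReport]  # learner -> CV report (baseline)
    weights: dict[str, float]  # learner -> ensemble weight
    mech: dict  # (period, season) -> {smr, vpd, resistance, hpa}


@dataclass
class Study:
    config: StudyConfig
    elevation: RasterGrid
    climates: dict[str, syn.MonthlyClimate]
    bioclims: dict[str, bc.BioclimStack]
    by_species: dict[str, SpeciesStudy]


def seasonal_smr(climate: syn.MonthlyClimate, mass: RasterGrid,
                 coef: phys.SmrCoefficients, season: str,
                 species: str = "synthetic") -> phys.SmrSurface:
    """Monthly SMR from monthly mean temperature, averaged over the season."""
    months = bc.SEASON_MONTHS[season]
    monthly = [phys.compute_smr(climate.tmean(m), mass, coef, species, season,
                                climate.period_label).vo2 for m in months]
    mask = np.logical_or.reduce([g.nodata_mask for g in monthly])
    mean = np.mean([g.values for g in monthly], axis=0)
    return phys.SmrSurface(monthly[0].like(mean, mask), species, season,
                           climate.period_label)


def assemble_study(cfg: StudyConfig) -> Study:
    """Build every modelled surface of the study in memory."""
    cfg.scenario.validate()
    elevation = syn.generate_elevation(cfg.scenario)
    baseline = syn.generate_monthly_temperature(elevation, cfg.scenario,
                                                cfg.baseline_period())
    climates = {
        period: syn.apply_warming(baseline, offset, period)
        for period, offset in cfg.scenario.warming_offsets.items()
    }
    bioclims = {p: bc.derive_bioclim(c) for p, c in climates.items()}
    humidity = cfg.scenario.monthly_humidity()
    truth = syn.true_suitability(elevation, cfg.suitability_midpoint,
                                 cfg.suitability_steepness)
    base = cfg.baseline_period()

    by_species: dict[str, SpeciesStudy] = {}
    for sp_idx, params in enumerate(cfg.species):
        sp_seed = cfg.seed + 1000 * sp_idx
        occ = syn.sample_occurrences(truth, cfg.n_presences, sp_seed, params.label)
        n_bg = int(round(cfg.background_ratio * len(occ)))
        bg = syn.sample_background(elevation, max(n_bg, 1), sp_seed)
        mass_samples = phys.simulate_mass_samples(params, cfg.mass_sample_n, sp_seed)
        mass_model = phys.fit_mass_elevation(mass_samples, params.label)
        mass = phys.predict_mass(elevation, mass_model)

        surface, models, reports = sdm.fit_ensemble(
            occ, bg, bioclims[base], l2=cfg.sdm_l2, pct=cfg.sdm_pct,
            k=cfg.sdm_k, seed=sp_seed, weighting=cfg.sdm_weighting,
            species=params.label,
        )
        if cfg.sdm_weighting == "equal":
            weights = {name: 1.0 for name in models}
        else:
            weights = {name: max(reports[name].auc - 0.5, 0.0) for name in models}
            if sum(weights.values()) <= 0:
                weights = {name: 1.0 for name in models}

        surfaces, suitable = {}, {}
        for period in cfg.periods():
            if period == base:
                surf = surface
            else:
                members = [models[name].predict_surface(bioclims[period], params.label)
                           for name in models]
                surf = sdm.ensemble(members, list(weights.values()), params.label)
            surfaces[period] = surf
            suitable[period] = sdm.threshold_suitable(surf, cfg.sdm_cutoff)

        mech = {}
        for period in cfg.periods():
            for season in cfg.seasons:
                smr = seasonal_smr(climates[period], mass, params.smr, season, params.label)
                vpd = moist.seasonal_min_vpd(climates[period], humidity, season,
                                             elevation=elevation)
                res = resist.build_resistance(smr, vpd)
                hpa = resist.delineate_hpa(smr, vpd, elevation, params.elevation_range)
                mech[(period, season)] = {
                    "smr": smr, "vpd": vpd, "resistance": res, "hpa": hpa,
                }
        by_species[params.label] = SpeciesStudy(
            params, truth, occ, bg, mass_model, mass, surfaces, suitable,
            reports, weights, mech,
        )
    return Study(cfg, elevation, climates, bioclims, by_species)


# ---------------------------------------------------------------------------
# Full scenario run with artifacts
# ---------------------------------------------------------------------------


@dataclass
class PipelineRun:
    config: StudyConfig
    outdir: Path
    manifest: dict
    study: Study


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _bool_grid(mask: RasterGrid) -> RasterGrid:
    return mask.like(mask.values.astype(float), mask.nodata_mask.copy())


def run_scenario(cfg: StudyConfig, outdir) -> PipelineRun:
    """Run every stage and write rasters, tables, vectors and the manifest."""
    outdir = Path(outdir)
    for sub in ("rasters", "tables", "vectors"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    study = assemble_study(cfg)
    artifacts: dict[str, list[str]] = {
        "suitability": [], "threshold": [], "mechanistic": [],
        "agreement": [], "corridors": [], "fragmentation": [],
    }

    def save_raster(grid: RasterGrid, name: str, cls: str):
        path = outdir / "rasters" / f"{name}.tif"
        write_raster(grid, path)
        artifacts[cls].append(str(path.relative_to(outdir)))

    write_raster(study.elevation, outdir / "rasters" / "elevation.tif")

    eval_rows, agree_rows, layer_rows, curve_rows = [], [], [], []
    frag_rows, cost_rows = [], []
    seed_registry = {"study_seed": cfg.seed, "scenario_seed": cfg.scenario.seed}

    for label, sp in study.by_species.items():
        lo, hi = sp.params.elevation_range
        range_mask = study.elevation.like(
            (study.elevation.values >= lo) & (study.elevation.values <= hi))
        pts_seed = cfg.seed + 17
        seed_registry[f"{label}/agreement_points"] = pts_seed
        points = agr.sample_within(range_mask, cfg.agreement_n_points, pts_seed,
                                   "elevational range")
        ladder = cfg.resolution_ladder(study.elevation)

        for name, rep in sp.reports.items():
            eval_rows.append({
                "species": label, "learner": name, "auc": rep.auc,
                "tss": rep.tss, "cbi": rep.cbi, "k": rep.k,
                "weight": sp.weights[name],
            })

        for period in cfg.periods():
            surf = sp.surfaces[period]
            save_raster(surf.prob, f"suitability_{label}_{period}", "suitability")
            save_raster(_bool_grid(sp.suitable[period]),
                        f"suitable_{label}_{period}", "threshold")

            suit_pts = None
            suit_cells = int(sp.suitable[period].values.astype(bool).sum())
            if suit_cells >= 3:
                s_seed = cfg.seed + 29
                seed_registry[f"{label}/{period}/suitable_points"] = s_seed
                suit_pts = agr.sample_within(sp.suitable[period],
                                             cfg.agreement_n_points, s_seed,
                                             "highly suitable")

            for season in cfg.seasons:
                m = sp.mech[(period, season)]
                save_raster(m["smr"].vo2, f"smr_{label}_{period}_{season}", "mechanistic")
                save_raster(m["vpd"].vpd, f"vpd_{label}_{period}_{season}", "mechanistic")
                save_raster(m["resistance"].resistance,
                            f"resistance_{label}_{period}_{season}", "mechanistic")
                save_raster(_bool_grid(m["hpa"].mask),
                            f"hpa_{label}_{period}_{season}", "mechanistic")

                res_grid = m["resistance"].resistance
                rho = agr.correlate_surfaces(surf, res_grid, points)
                agree_rows.append((label, season, period, "range", rho, points.n))
                if suit_pts is not None:
                    rho_s = agr.correlate_surfaces(surf, res_grid, suit_pts)
                    agree_rows.append((label, season, period, "highly_suitable",
                                       rho_s, suit_pts.n))
                for lname, lgrid in (("smr", m["smr"].vo2), ("vpd", m["vpd"].vpd)):
                    layer_rows.append({
                        "species": label, "season": season, "period": period,
                        "layer": lname,
                        "rho": agr.correlate_surfaces(surf, lgrid, points),
                    })
                curve = agr.multiresolution_agreement(surf, res_grid, points, ladder)
                conv = agr.convergence_resolution(curve)
                for r, rho_r, n_r in zip(curve.resolutions, curve.rho, curve.n_effective):
                    curve_rows.append({
                        "species": label, "season": season, "period": period,
                        "resolution_m": r,
                        "rho": np.nan if rho_r is None else rho_r,
                        "n_effective": n_r,
                        "convergence_resolution_m":
                            np.nan if conv is None else conv,
                    })

            # corridors + fragmentation per period
            cores = conn.extract_core_areas(sp.suitable[period],
                                            cfg.min_core_area_km2, cfg.connectivity)
            for season in cfg.seasons:
                m = sp.mech[(period, season)]
                if cores.n_cores < 2:
                    log.warning("%s %s %s: %d core(s); corridors skipped",
                                label, period, season, cores.n_cores)
                    frag_rows.append({
                        "species": label, "season": season, "period": period,
                        "n_cores": cores.n_cores, "n_patches": 0,
                        "enn_mean_m": np.nan, "enn_sd_m": np.nan,
                        "pd_per_ha": np.nan, "pa_mean": np.nan,
                        "mean_lcp_km": np.nan,
                    })
                    continue
                paths, failures = conn.all_pair_paths(m["resistance"].resistance, cores)
                for a, b, msg in failures:
                    log.warning("%s %s %s: %s", label, period, season, msg)
                corr = conn.buffer_corridors(paths, study.elevation, cfg.buffer_radius_m)
                gj = conn.paths_to_geojson(paths, study.elevation)
                gj_path = outdir / "vectors" / f"corridors_{label}_{period}_{season}.geojson"
                conn.write_geojson(gj, gj_path)
                artifacts["corridors"].append(str(gj_path.relative_to(outdir)))
                for p in paths:
                    cost_rows.append({
                        "species": label, "season": season, "period": period,
                        "source": p.source_label, "target": p.target_label,
                        "accumulated_cost": p.accumulated_cost,
                        "path_length_m": p.path_length,
                        "euclidean_length_m": p.euclidean_length,
                    })
                rep = frag.compute_fragmentation(sp.suitable[period], corr,
                                                 cfg.connectivity)
                frag_rows.append({
                    "species": label, "season": season, "period": period,
                    "n_cores": cores.n_cores, "n_patches": rep.n_patches,
                    "enn_mean_m": rep.enn_mean, "enn_sd_m": rep.enn_sd,
                    "pd_per_ha": rep.pd, "pa_mean": rep.pa_mean,
                    "mean_lcp_km": float(np.mean([p.path_length for p in paths]) / 1e3)
                    if paths else np.nan,
                })

    tables = {
        "evaluation": pd.DataFrame(eval_rows),
        "agreement": agr.agreement_table(agree_rows).rows,
        "agreement_layers": pd.DataFrame(layer_rows),
        "resolution_curves": pd.DataFrame(curve_rows),
        "fragmentation": pd.DataFrame(frag_rows),
        "pairwise_costs": pd.DataFrame(cost_rows),
    }
    table_class = {
        "evaluation": "agreement", "agreement": "agreement",
        "agreement_layers": "agreement", "resolution_curves": "agreement",
        "fragmentation": "fragmentation", "pairwise_costs": "corridors",
    }
    for name, df in tables.items():
        path = outdir / "tables" / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        artifacts[table_class[name]].append(str(path.relative_to(outdir)))
    with open(outdir / "tables" / "evaluation.json", "w") as fh:
        json.dump(eval_rows, fh, sort_keys=True, indent=1)
    cfg.to_yaml(outdir / "config.yaml")

    manifest = {
        "artifacts": artifacts,
        "seed_registry": seed_registry,
        "files": {},
    }
    for sub in ("rasters", "tables", "vectors"):
        for path in sorted((outdir / sub).glob("*")):
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    manifest["files"]["config.yaml"] = _sha256(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return PipelineRun(cfg, outdir, manifest, study)
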