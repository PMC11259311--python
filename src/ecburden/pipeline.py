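"""Pipeline orchestration: simulate -> regrid -> train -> predict ->
aggregate -> burden, with a reproducibility manifest.

Each stage writes its outputs under the run directory and is timed;
the manifest records the config hash, per-stage seeds (derived from
the shared seed by stable hashing of stage names), file checksums and
the package version, so identical config + seed reproduces identical
checksums for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (ExposureSurface, annual_stack, national_series,
                        regional_series, regional_trends, seasonal_mean)
from .burden import BurdenResult, CounterfactualSpec, ExposureResponse, compute_burden
from .config import RunConfig
from .expomodel import (ExposureRandomForest, build_training_table, evaluate,
                        fit_exposure_model, permutation_importance,
                        predict_daily_surface, save_model)
from .grid import regrid_stack
from .io import (sha256_file, write_csv, write_dataarray, write_predictor_dir,
                 write_region_map_csv, write_regions_geojson)
from .synth import SynthConfig, TruthBundle, generate_predictor_fields, generate_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    stage_seconds: dict[str, float] = dc_field(default_factory=dict)
    file_checksums: dict[str, str] = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage substream seed by stable hashing of the stage name."""
    h = hashlib.sha256(f"{seed}|{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def synth_config(cfg: RunConfig, seed: int | None = None) -> SynthConfig:
    s = cfg.synth
    return SynthConfig(
        grid_nx=s.grid_nx, grid_ny=s.grid_ny, cell_size_km=s.cell_size_km,
        n_regions=s.n_regions, years=tuple(s.years), n_sites=s.n_sites,
        obs_missing_rate=s.obs_missing_rate, noise_sd=s.noise_sd,
        obs_noise_sd=s.obs_noise_sd, spatial_range_km=s.spatial_range_km,
        seed=stage_seed(cfg.seed if seed is None else seed, "simulate"),
        true_coefficients=s.true_coefficients,
        seasonal_amplitude=s.seasonal_amplitude, intercept=s.intercept,
        emission_trend_per_year=s.emission_trend_per_year,
        trend_regions=tuple(s.trend_regions),
        swath_gap=tuple(s.swath_gap) if s.swath_gap else None,
        swath_gap_period=s.swath_gap_period,
    )


@dataclass
class RunResult:
    """In-memory handles to every stage product of a run."""

    manifest: RunManifest
    bundle: TruthBundle
    model: ExposureRandomForest
    evaluation: pd.DataFrame
    importance: pd.DataFrame
    surface: ExposureSurface
    annual: "object"
    regional: pd.DataFrame
    trends: pd.DataFrame
    national: pd.Series
    burden: BurdenResult


def run_all(cfg: RunConfig, out_dir: str | Path | None = None,
            seed: int | None = None) -> RunResult:
    """Execute all stages in order, writing outputs and the manifest."""
    out = Path(out_dir if out_dir is not None else cfg.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    manifest = RunManifest(config_hash=config_hash(cfg), seed=seed,
                           software_version=__version__)
    written: list[Path] = []

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", stage)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest.stage_seconds[stage] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(stage, str(exc)) from exc
                return False
        return _T()

    # -- simulate -----------------------------------------------------
    with timed("simulate"):
        scfg = synth_config(cfg, seed)
        native = generate_predictor_fields(scfg)
        bundle = generate_truth(scfg, native)
        sim_dir = out / "synthetic"
        written += write_predictor_dir(native, sim_dir / "predictors")
        written.append(write_dataarray(bundle.true_ec, sim_dir / "true_ec.nc"))
        written.append(write_dataarray(bundle.population, sim_dir / "population.nc"))
        written.append(write_csv(bundle.sites, sim_dir / "sites.csv"))
        written.append(write_csv(bundle.monitors, sim_dir / "monitors.csv"))
        written.append(write_csv(bundle.demographics, sim_dir / "demographics.csv"))
        written.append(write_region_map_csv(bundle.grid, sim_dir / "region_map.csv"))
        written.append(write_regions_geojson(bundle.grid, sim_dir / "regions.geojson"))

    # -- regrid -------------------------------------------------------
    with timed("regrid"):
        gridded = regrid_stack(native, bundle.grid,
                               idw_power=cfg.model.idw_power,
                               idw_k_neighbors=cfg.model.idw_k_neighbors)
        # Carry the synthetic swath-gap mask (if any) from the bundle.
        if scfg.swath_gap is not None:
            for name in ("aod_total", "aod_band8", "aod_band14"):
                gap = ~np.isfinite(bundle.gridded[name].values.values)
                vals = gridded[name].values.values
                vals[gap] = np.nan
        rg_dir = out / "regridded"
        written += write_predictor_dir({n: f.values for n, f in gridded.items()}, rg_dir)

    # -- train --------------------------------------------------------
    with timed("train"):
        table = build_training_table(bundle.monitors, bundle.sites, gridded, bundle.grid)
        model = fit_exposure_model(table, n_trees=cfg.model.n_trees,
                                   seed=stage_seed(seed, "train"),
                                   max_features=cfg.model.max_features,
                                   max_depth=cfg.model.max_depth)
        rep_daily = evaluate(model, table, "daily")
        rep_monthly = evaluate(model, table, "monthly",
                               min_monthly_obs=cfg.aggregation.min_monthly_obs)
        evaluation = pd.DataFrame([rep_daily.__dict__, rep_monthly.__dict__])
        importance = permutation_importance(model, table, n_repeats=5,
                                            seed=stage_seed(seed, "importance"))
        tr_dir = out / "model"
        written.append(write_csv(table.frame, tr_dir / "training_table.csv"))
        (tr_dir / "drop_log.json").parent.mkdir(parents=True, exist_ok=True)
        (tr_dir / "drop_log.json").write_text(json.dumps(table.dropped, indent=2))
        written.append(tr_dir / "drop_log.json")
        save_model(model, tr_dir / "model.joblib")
        written.append(tr_dir / "model.joblib")
        written.append(write_csv(evaluation, tr_dir / "evaluation.csv"))
        written.append(write_csv(importance.reset_index(), tr_dir / "importance.csv"))

    # -- predict ------------------------------------------------------
    with timed("predict"):
        pred = predict_daily_surface(model, gridded, bundle.grid, dates=scfg.dates())
        surface = ExposureSurface(daily=pred)
        written.append(write_dataarray(pred, out / "surface" / "ec_daily.nc"))

    # -- aggregate ----------------------------------------------------
    with timed("aggregate"):
        annual = annual_stack(surface, min_days=cfg.aggregation.min_valid_days)
        regional = regional_series(annual, bundle.population, bundle.grid,
                                   weighted=cfg.aggregation.weighted)
        national = national_series(annual, bundle.population)
        trends = (regional_trends(regional) if len(scfg.years) >= 3
                  else pd.DataFrame(columns=["region", "slope", "pct_change", "pct_change_raw"]))
        ag_dir = out / "aggregate"
        written.append(write_dataarray(annual, ag_dir / "ec_annual.nc"))
        for season in ("spring", "summer", "autumn", "winter"):
            da = seasonal_mean(surface, season)
            written.append(write_dataarray(da, ag_dir / f"ec_{season}.nc"))
        written.append(write_csv(regional, ag_dir / "regional_series.csv"))
        written.append(write_csv(trends, ag_dir / "regional_trends.csv"))
        written.append(write_csv(national.rename_axis("year").reset_index(),
                                 ag_dir / "national_series.csv"))

    # -- burden -------------------------------------------------------
    with timed("burden"):
        if cfg.paths.demographics_csv is not None:
            demo_path = Path(cfg.paths.demographics_csv)
            if not demo_path.exists():
                raise FileNotFoundError(f"demographics file not found: {demo_path}")
            demographics = pd.read_csv(demo_path)
        else:
            demographics = bundle.demographics
        er = ExposureResponse(beta=cfg.exposure_response.beta,
                              beta_low=cfg.exposure_response.beta_low,
                              beta_high=cfg.exposure_response.beta_high,
                              per_ugm3=cfg.exposure_response.per_ugm3)
        cfspec = CounterfactualSpec(mode=cfg.counterfactual.mode,
                                    value=cfg.counterfactual.value)
        result = compute_burden(annual, bundle.population, bundle.grid.region_of,
                                demographics, er=er, cf=cfspec,
                                allocation=cfg.burden.allocation)
        bd_dir = out / "burden"
        written.append(write_csv(result.region_year, bd_dir / "burden_region_year.csv"))
        written.append(write_csv(result.national, bd_dir / "burden_national.csv"))
        written.append(write_csv(result.cumulative, bd_dir / "burden_cumulative.csv"))
        written.append(write_csv(result.coverage, bd_dir / "coverage.csv"))

    for path in written:
        manifest.file_checksums[str(Path(path).relative_to(out))] = sha256_file(path)
    (out / "manifest.json").write_text(manifest.to_json())

    return RunResult(manifest=manifest, bundle=bundle, model=model,
                     evaluation=evaluation, importance=importance,
                     surface=surface, annual=annual, regional=regional,
                     trends=trends, national=national, burden=result)
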