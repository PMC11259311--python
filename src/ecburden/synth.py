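"""Synthetic study-system generator.

Emulates, at desk scale, the data constellation behind a national
elemental-carbon (EC) exposure and burden analysis: thirteen spatially
autocorrelated predictor fields on heterogeneous native lattices
(roads, population density, reanalysis black carbon, EC emissions,
satellite aerosol optical depths, vegetation, cloud fraction,
meteorology, visibility), a latent daily EC field that is a known
nonlinear (softplus-linked) seasonal function of a subset of those
predictors, a sparse ground-monitoring network with day-level
missingness, a gridded adult (>= 25 y) population, and region-level
baseline mortality rates.

Because the latent truth is known, every downstream stage — regridding,
the tree-ensemble exposure model, aggregation and the attributable-
mortality computation — can be validated against ground truth.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .grid import GridDefinition, RegriddedField, expand_daily, regrid_stack

logger = logging.getLogger(__name__)

__all__ = [
    "PREDICTOR_NAMES",
    "SynthConfig",
    "TruthBundle",
    "generate_predictor_fields",
    "generate_truth",
    "make_region_map",
    "softplus",
]


@dataclass(frozen=True)
class _PredictorSpec:
    native_factor: float  # native cell size as a multiple of the analysis cell
    temporal: str         # 'static' | 'monthly' | 'daily'
    mean: float
    sd: float
    units: str


# Thirteen predictors, on (at least) three distinct native resolutions,
# mirroring the mix of fine satellite products, mid-resolution
# meteorology and coarse reanalysis/emission grids.
PREDICTOR_SPECS: dict[str, _PredictorSpec] = {
    "road_length":        _PredictorSpec(1.0,  "static",  8.0,   5.0,  "km"),
    "population_density": _PredictorSpec(0.5,  "static",  300.0, 250.0, "km-2"),
    "bc_concentration":   _PredictorSpec(5.0,  "daily",   2.0,   1.0,  "ug m-3"),
    "ec_emission":        _PredictorSpec(8.0,  "monthly", 1.0,   0.6,  "Mg month-1"),
    "aod_total":          _PredictorSpec(0.5,  "daily",   0.45,  0.20, "1"),
    "aod_band8":          _PredictorSpec(0.5,  "daily",   0.06,  0.03, "1"),
    "aod_band14":         _PredictorSpec(0.5,  "daily",   0.04,  0.02, "1"),
    "ndvi":               _PredictorSpec(0.5,  "monthly", 0.4,   0.15, "1"),
    "cloud_fraction":     _PredictorSpec(10.0, "monthly", 0.5,   0.15, "1"),
    "wind_direction":     _PredictorSpec(2.5,  "daily",   180.0, 60.0, "degree"),
    "wind_speed":         _PredictorSpec(2.5,  "daily",   3.5,   1.5,  "m s-1"),
    "pblh":               _PredictorSpec(2.5,  "daily",   800.0, 300.0, "m"),
    "visibility":         _PredictorSpec(3.0,  "daily",   15.0,  6.0,  "km"),
}

PREDICTOR_NAMES: tuple[str, ...] = tuple(PREDICTOR_SPECS)

# Default effect weights (per standard deviation of the regridded
# predictor, on the softplus-link scale).  Predictors absent from the
# map are pure decoys and exist to exercise importance recovery.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "road_length": 0.8,
    "bc_concentration": 0.6,
    "ec_emission": 0.5,
    "aod_band8": 0.35,
    "aod_total": 0.25,
    "wind_speed": -0.3,
    "pblh": -0.35,
    "visibility": -0.25,
}

_AR1_RHO_DAILY = 0.8  # day-to-day persistence of time-varying fields


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic study system.

    Defaults define the reference desk-scale study: a 20 x 20 grid of
    10 km cells partitioned into 5 contiguous regions, two calendar
    years, 30 monitoring sites (matching the sparse national network
    the analysis assumes), 20 % site-day missingness, moderate process
    and observation noise, and a winter-peaking seasonal cycle.
    """

    grid_nx: int = 20
    grid_ny: int = 20
    cell_size_km: float = 10.0
    n_regions: int = 5
    years: tuple[int, ...] = (2012, 2013)
    n_sites: int = 30
    obs_missing_rate: float = 0.2
    noise_sd: float = 0.3          # process noise inside the softplus link, ug m-3
    obs_noise_sd: float = 0.2      # additive monitor observation noise, ug m-3
    spatial_range_km: float = 30.0
    seed: int = 0
    true_coefficients: Mapping[str, float] | None = None
    seasonal_amplitude: float = 0.6  # winter-peaking sinusoid, link scale
    intercept: float = 2.2           # link-scale baseline
    emission_trend_per_year: float = -0.08  # native units yr-1, trend regions only
    trend_regions: tuple[int, ...] = (0, 1)
    swath_gap: tuple[float, float, float, float] | None = None  # (x0,x1,y0,y1) fractions
    swath_gap_period: int = 2  # gap applies every k-th day

    def __post_init__(self) -> None:
        if self.grid_nx < 4 or self.grid_ny < 4:
            raise ValueError("grid_nx and grid_ny must be >= 4")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        if not (2 <= self.n_regions <= self.grid_nx * self.grid_ny):
            raise ValueError("n_regions must be in [2, n_cells]")
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if not (0 <= self.obs_missing_rate < 1):
            raise ValueError("obs_missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        years = tuple(int(y) for y in self.years)
        if not years or list(years) != list(range(years[0], years[-1] + 1)):
            raise ValueError("years must be consecutive calendar years")
        object.__setattr__(self, "years", years)
        if self.true_coefficients is not None:
            unknown = set(self.true_coefficients) - set(PREDICTOR_NAMES)
            if unknown:
                raise ValueError(f"unknown predictor name(s) in true_coefficients: {sorted(unknown)}")

    @property
    def coefficients(self) -> dict[str, float]:
        base = DEFAULT_TRUE_COEFFICIENTS if self.true_coefficients is None else self.true_coefficients
        return {name: float(base.get(name, 0.0)) for name in PREDICTOR_NAMES}

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(f"{self.years[0]}-01-01", f"{self.years[-1]}-12-31", freq="D")


@dataclass
class TruthBundle:
    """Everything the synthetic world knows about itself."""

    config: SynthConfig
    grid: GridDefinition
    predictors: dict[str, xr.DataArray]          # native-resolution stacks
    gridded: dict[str, RegriddedField]           # regridded onto the analysis grid
    true_ec: xr.DataArray                        # (time, y, x), ug m-3
    sites: pd.DataFrame                          # site_id, ix, iy, x_km, y_km
    monitors: pd.DataFrame                       # site_id, date, ec_obs
    population: xr.DataArray                     # (y, x) adult (>=25 y) counts
    demographics: pd.DataFrame                   # region, year, pop_25plus, baseline_rate
    region_map: xr.DataArray                     # (y, x) region ids


def softplus(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable softplus link, log(1 + e^z)."""
    return np.logaddexp(0.0, z)


def _subrng(seed: int, *tags: str) -> np.random.Generator:
    h = hashlib.sha256(("%d|" % seed + "|".join(tags)).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def _smooth_field(rng: np.random.Generator, ny: int, nx: int, sigma_cells: float) -> np.ndarray:
    """Unit-variance Gaussian field with correlation length ~ sigma_cells.

    The flat-field limit (infinite range) collapses to a single random
    value shared by every cell.
    """
    if not np.isfinite(sigma_cells):
        return np.full((ny, nx), rng.standard_normal())
    z = rng.standard_normal((ny, nx))
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        sd = z.std()
        if sd > 1e-12:
            z = (z - z.mean()) / sd
    return z


def _native_axes(cfg: SynthConfig, native_km: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates of a native lattice covering the domain."""
    ext_x = cfg.grid_nx * cfg.cell_size_km
    ext_y = cfg.grid_ny * cfg.cell_size_km
    n_x = max(1, int(np.ceil(ext_x / native_km)))
    n_y = max(1, int(np.ceil(ext_y / native_km)))
    xs = (np.arange(n_x) + 0.5) * native_km
    ys = (np.arange(n_y) + 0.5) * native_km
    return ys, xs


def make_region_map(cfg: SynthConfig) -> np.ndarray:
    """Contiguous region partition: nearest-seed (Voronoi) assignment."""
    rng = _subrng(cfg.seed, "regions")
    nx, ny = cfg.grid_nx, cfg.grid_ny
    seeds = rng.choice(nx * ny, size=cfg.n_regions, replace=False)
    sy, sx = np.divmod(seeds, nx)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    d2 = (yy[..., None] - sy) ** 2 + (xx[..., None] - sx) ** 2
    return np.argmin(d2, axis=-1).astype(int)


def _month_starts(cfg: SynthConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{cfg.years[0]}-01-01", f"{cfg.years[-1]}-12-01", freq="MS")


def generate_predictor_fields(cfg: SynthConfig) -> dict[str, xr.DataArray]:
    """Generate the 13 named predictor fields on their native lattices.

    Each field is spatially autocorrelated with correlation length
    about ``spatial_range_km``; time-varying fields evolve as an AR(1)
    process in their native time step.  The ec_emission field carries a
    configurable declining linear trend inside the "first-tier" trend
    regions, emulating early, strict regulation there.  Deterministic
    given the seed.
    """
    region_map = make_region_map(cfg)
    dates = cfg.dates()
    months = _month_starts(cfg)
    out: dict[str, xr.DataArray] = {}
    for name, spec in PREDICTOR_SPECS.items():
        native_km = spec.native_factor * cfg.cell_size_km
        ys, xs = _native_axes(cfg, native_km)
        ny, nx = len(ys), len(xs)
        sigma = cfg.spatial_range_km / native_km if np.isfinite(cfg.spatial_range_km) else np.inf
        rng = _subrng(cfg.seed, "fields", name)
        if spec.temporal == "static":
            z = _smooth_field(rng, ny, nx, sigma)
            da = xr.DataArray(spec.mean + spec.sd * z, dims=("y", "x"),
                              coords={"y": ys, "x": xs}, name=name)
        else:
            times = dates if spec.temporal == "daily" else months
            rho = _AR1_RHO_DAILY if spec.temporal == "daily" else 0.6
            fields = np.empty((len(times), ny, nx))
            z = _smooth_field(rng, ny, nx, sigma)
            fields[0] = z
            innov = np.sqrt(1.0 - rho**2)
            for t in range(1, len(times)):
                z = rho * z + innov * _smooth_field(rng, ny, nx, sigma)
                fields[t] = z
            vals = spec.mean + spec.sd * fields
            if name == "ec_emission" and cfg.emission_trend_per_year != 0.0 and cfg.trend_regions:
                vals = vals + _emission_trend(cfg, region_map, ys, xs, times)
            da = xr.DataArray(vals, dims=("time", "y", "x"),
                              coords={"time": times, "y": ys, "x": xs}, name=name)
        da.attrs.update(units=spec.units, temporal=spec.temporal, native_cell_km=native_km)
        out[name] = da
    return out


def _emission_trend(cfg: SynthConfig, region_map: np.ndarray,
                    ys: np.ndarray, xs: np.ndarray, times: pd.DatetimeIndex) -> np.ndarray:
    """Additive declining trend on native emission cells in trend regions."""
    # Map native cell centers to analysis cells, then to regions.
    ix = np.clip((xs // cfg.cell_size_km).astype(int), 0, cfg.grid_nx - 1)
    iy = np.clip((ys // cfg.cell_size_km).astype(int), 0, cfg.grid_ny - 1)
    reg = region_map[np.ix_(iy, ix)]
    in_trend = np.isin(reg, np.asarray(cfg.trend_regions))
    t_years = (times.year - cfg.years[0]) + (times.month - 1) / 12.0
    ramp = cfg.emission_trend_per_year * np.asarray(t_years)
    return ramp[:, None, None] * in_trend[None, :, :]


def _standardize(a: np.ndarray) -> np.ndarray:
    m = np.nanmean(a)
    s = np.nanstd(a)
    if not np.isfinite(s) or s < 1e-12:
        return np.zeros_like(a)
    return (a - m) / s


def _apply_swath_gap(cfg: SynthConfig, gridded: dict[str, RegriddedField]) -> None:
    """NaN out AOD predictors inside a rectangular box on periodic days."""
    if cfg.swath_gap is None:
        return
    fx0, fx1, fy0, fy1 = cfg.swath_gap
    x0 = int(np.floor(fx0 * cfg.grid_nx))
    x1 = max(x0 + 1, int(np.ceil(fx1 * cfg.grid_nx)))
    y0 = int(np.floor(fy0 * cfg.grid_ny))
    y1 = max(y0 + 1, int(np.ceil(fy1 * cfg.grid_ny)))
    for name in ("aod_total", "aod_band8", "aod_band14"):
        da = gridded[name].values
        vals = da.values
        gap_days = np.arange(vals.shape[0]) % cfg.swath_gap_period == 0
        vals[np.ix_(gap_days, np.arange(y0, y1), np.arange(x0, x1))] = np.nan
        logger.info("swath gap applied to %s: %d days, box x[%d:%d] y[%d:%d]",
                    name, int(gap_days.sum()), x0, x1, y0, y1)


def generate_truth(cfg: SynthConfig, predictors: Mapping[str, xr.DataArray]) -> TruthBundle:
    """Build the latent EC field, monitors, population and demographics.

    The latent truth is softplus(intercept + sum_p c_p z_p + seasonal
    sinusoid + process noise), where z_p are the regridded predictors
    standardized over all cell-days — so the truth is, by construction,
    a function of exactly the features the exposure model will see.
    """
    region_map = make_region_map(cfg)
    grid = GridDefinition(cfg.grid_nx, cfg.grid_ny, cfg.cell_size_km, region_of=region_map)
    dates = cfg.dates()
    coefs = cfg.coefficients

    gridded = regrid_stack(predictors, grid)
    daily = {name: expand_daily(f.values, dates) for name, f in gridded.items()}

    link = np.full((len(dates), grid.ny, grid.nx), float(cfg.intercept))
    for name, c in coefs.items():
        if c != 0.0:
            link += c * _standardize(daily[name].values)
    doy = dates.dayofyear.to_numpy()
    link += cfg.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)[:, None, None]
    if cfg.noise_sd > 0:
        rng_noise = _subrng(cfg.seed, "truth-noise")
        link += rng_noise.normal(0.0, cfg.noise_sd, size=link.shape)
    true_ec = xr.DataArray(softplus(link), dims=("time", "y", "x"),
                           coords={"time": dates, **grid.coords()},
                           name="true_ec", attrs={"units": "ug m-3"})

    # Adult population from the population-density predictor (clipped).
    dens = gridded["population_density"].values.values
    pop = np.clip(dens, 5.0, None) * grid.cell_area_km2
    population = xr.DataArray(pop, dims=("y", "x"), coords=grid.coords(),
                              name="population", attrs={"units": "persons (>=25 y)"})

    # Region-level baseline mortality, constant over years.
    rng_demo = _subrng(cfg.seed, "demographics")
    region_ids = np.unique(region_map)
    rates = {int(r): float(rng_demo.uniform(0.007, 0.011)) for r in region_ids}
    rows = []
    for r in region_ids:
        pop_r = float(pop[region_map == r].sum())
        for y in cfg.years:
            rows.append({"region": int(r), "year": int(y),
                         "pop_25plus": pop_r, "baseline_rate": rates[int(r)]})
    demographics = pd.DataFrame(rows)

    # Monitors: preferential placement in populous cells, snapped to
    # cell centers, i.i.d. Bernoulli site-day missingness.
    rng_sites = _subrng(cfg.seed, "monitor-sites")
    p = pop.ravel() / pop.sum()
    chosen = rng_sites.choice(grid.n_cells, size=cfg.n_sites, replace=False, p=p)
    iy, ix = np.divmod(chosen, grid.nx)
    sites = pd.DataFrame({
        "site_id": [f"S{i:03d}" for i in range(cfg.n_sites)],
        "ix": ix, "iy": iy,
        "x_km": grid.x_centers[ix], "y_km": grid.y_centers[iy],
        "region": region_map[iy, ix],
    })

    rng_obs = _subrng(cfg.seed, "monitor-obs")
    truth_at_sites = true_ec.values[:, iy, ix]  # (time, site)
    obs = truth_at_sites.copy()
    if cfg.obs_noise_sd > 0:
        obs = obs + rng_obs.normal(0.0, cfg.obs_noise_sd, size=obs.shape)
    keep = np.ones(obs.shape, dtype=bool)
    if cfg.obs_missing_rate > 0:
        rng_miss = _subrng(cfg.seed, "monitor-missing")
        keep = rng_miss.random(obs.shape) >= cfg.obs_missing_rate
    t_idx, s_idx = np.nonzero(keep)
    monitors = pd.DataFrame({
        "site_id": sites["site_id"].to_numpy()[s_idx],
        "date": dates[t_idx],
        "ec_obs": obs[t_idx, s_idx],
    }).sort_values(["site_id", "date"], ignore_index=True)

    _apply_swath_gap(cfg, gridded)

    region_da = xr.DataArray(region_map, dims=("y", "x"), coords=grid.coords(), name="region")
    return TruthBundle(
        config=cfg, grid=grid, predictors=dict(predictors), gridded=gridded,
        true_ec=true_ec, sites=sites, monitors=monitors,
        population=population, demographics=demographics, region_map=region_da,
    )


def simulate(cfg: SynthConfig) -> TruthBundle:
    """Convenience wrapper: predictors then truth in one call."""
    return generate_truth(cfg, generate_predictor_fields(cfg))


def with_obs_noise(cfg: SynthConfig, obs_noise_sd: float) -> SynthConfig:
    """Same world, different monitor noise (all other substreams unchanged)."""
    return replace(cfg, obs_noise_sd=obs_noise_sd)
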