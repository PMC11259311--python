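"""Temporal and spatial aggregation of daily exposure surfaces.

Daily cell-level EC predictions are collapsed to annual and seasonal
means (respecting the missingness mask and a minimum-valid-days rule),
then to population-weighted regional and national concentrations, and
finally to per-region linear trends over the study period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grid import GridDefinition

logger = logging.getLogger(__name__)

SEASONS: dict[str, tuple[int, ...]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


@dataclass
class ExposureSurface:
    """Daily EC predictions on the analysis grid, NaN where masked."""

    daily: xr.DataArray  # (time, y, x), ug m-3

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.daily.coords["time"].values)

    @property
    def years(self) -> list[int]:
        return sorted(set(self.dates.year))


def _masked_mean(values: np.ndarray, min_days: int) -> np.ndarray:
    """Mean over axis 0 of valid days; cells below min_days are NaN."""
    valid = np.isfinite(values)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(valid, values, 0.0), axis=0) / np.maximum(n_valid, 1)
    return np.where(n_valid >= max(min_days, 1), mean, np.nan)


def annual_mean(surface: ExposureSurface, year: int, min_days: int = 60) -> xr.DataArray:
    """Per-cell mean over the year's valid days.

    A cell-year with fewer than ``min_days`` valid daily values is
    masked (NaN) rather than reported from thin coverage.
    """
    if year not in surface.years:
        raise ValueError(f"year {year} outside the surface period {surface.years}")
    sel = surface.daily.sel(time=surface.dates.year == year)
    out = xr.DataArray(
        _masked_mean(sel.values, min_days),
        dims=("y", "x"),
        coords={"y": surface.daily.coords["y"], "x": surface.daily.coords["x"]},
        name="ec_annual", attrs={"units": "ug m-3", "year": int(year)},
    )
    return out


def annual_stack(surface: ExposureSurface, min_days: int = 60) -> xr.DataArray:
    """(year, y, x) stack of annual means over the whole period."""
    years = surface.years
    das = [annual_mean(surface, y, min_days=min_days) for y in years]
    out = xr.concat([d.drop_attrs() for d in das], dim=pd.Index(years, name="year"))
    out.name = "ec_annual"
    out.attrs["units"] = "ug m-3"
    return out


def seasonal_mean(
    surface: ExposureSurface,
    season: str,
    year: int | None = None,
    min_days: int = 15,
) -> xr.DataArray:
    """Per-cell mean over a season's valid days.

    Winter straddles calendar years: December of year y belongs with
    January-February of year y+1.  With ``year=None`` the mean spans
    the whole period (December of the final study year is dropped, its
    winter being truncated by the period end); with an explicit year,
    months falling outside the period are excluded and logged.
    """
    if season not in SEASONS:
        raise ValueError(f"season must be one of {sorted(SEASONS)}")
    months = SEASONS[season]
    dates = surface.dates
    first_year, last_year = dates.year.min(), dates.year.max()

    if season != "winter":
        keep = np.isin(dates.month, months)
        if year is not None:
            keep &= dates.year == year
    else:
        # Assign each winter day to the December-anchored season-year.
        season_year = np.where(dates.month == 12, dates.year, dates.year - 1)
        keep = np.isin(dates.month, months)
        if year is None:
            drop_dec = keep & (dates.month == 12) & (dates.year == last_year)
            if drop_dec.any():
                logger.info(
                    "winter mean: dropping December %d (%d days), season truncated by period end",
                    last_year, int(drop_dec.sum()))
            keep &= ~drop_dec
        else:
            keep &= season_year == year
            out_months = []
            if year == last_year:
                out_months.append(f"Jan-Feb {year + 1}")
            if not keep.any():
                raise ValueError(f"winter {year} has no days inside the period")
            if out_months:
                logger.info("winter %d mean excludes out-of-period months: %s",
                            year, ", ".join(out_months))
    if year is not None and season != "winter" and not keep.any():
        raise ValueError(f"{season} {year} has no days inside the period")

    sel = surface.daily.values[keep]
    out = xr.DataArray(
        _masked_mean(sel, min_days),
        dims=("y", "x"),
        coords={"y": surface.daily.coords["y"], "x": surface.daily.coords["x"]},
        name=f"ec_{season}", attrs={"units": "ug m-3", "season": season},
    )
    if year is not None:
        out.attrs["year"] = int(year)
    _ = first_year  # anchors the season-year convention above
    return out


def population_weighted_mean(
    cell_values: xr.DataArray | np.ndarray,
    population: xr.DataArray | np.ndarray,
    member: np.ndarray | None = None,
) -> float:
    """Population-weighted mean over (a subset of) unmasked cells.

    ``member`` selects the region's cells (boolean, same shape); by
    default every cell belongs.  Masked cells and zero-population
    cells carry no weight; if no weight remains, raises.
    """
    x = np.asarray(cell_values, dtype=float)
    w = np.asarray(population, dtype=float)
    if x.shape != w.shape:
        raise ValueError("cell values and population shapes differ")
    sel = np.ones(x.shape, dtype=bool) if member is None else np.asarray(member, dtype=bool)
    ok = sel & np.isfinite(x) & (w > 0)
    if not ok.any():
        raise ValueError("no unmasked member cell with positive population")
    return float(np.sum(w[ok] * x[ok]) / np.sum(w[ok]))


@dataclass
class TrendResult:
    """OLS trend of an annual series."""

    slope: float            # ug m-3 yr-1
    intercept: float
    pct_change: float       # % change over the period, from trend-line endpoints
    pct_change_raw: float   # % change from the raw first/last values


def linear_trend(series: Mapping[int, float] | pd.Series) -> TrendResult:
    """OLS slope of value on year, plus percent change over the period.

    Percent change is computed from the fitted line's endpoint values
    (the raw first/last variant is also reported).
    """
    s = pd.Series(dict(series)).sort_index().astype(float)
    if len(s) < 3:
        raise ValueError("need at least 3 years for a trend")
    years = s.index.to_numpy(dtype=float)
    fit = stats.linregress(years, s.to_numpy())
    y0 = fit.intercept + fit.slope * years[0]
    y1 = fit.intercept + fit.slope * years[-1]
    pct = 100.0 * (y1 - y0) / y0 if y0 != 0 else np.nan
    raw = 100.0 * (s.iloc[-1] - s.iloc[0]) / s.iloc[0] if s.iloc[0] != 0 else np.nan
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept),
                       pct_change=float(pct), pct_change_raw=float(raw))


def regional_series(
    annual: xr.DataArray,
    population: xr.DataArray | np.ndarray,
    grid: GridDefinition,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-region, per-year (population-weighted) mean EC.

    Columns: region, year, pw_mean.  With ``weighted=False`` an
    unweighted mean over unmasked member cells is returned instead.
    """
    if grid.region_of is None:
        raise ValueError("grid has no region partition")
    pop = np.asarray(population, dtype=float)
    years = [int(y) for y in np.atleast_1d(annual.coords["year"].values)]
    rows = []
    for yr in years:
        vals = annual.sel(year=yr).values
        for r in grid.region_ids:
            member = grid.region_of == r
            if weighted:
                m = population_weighted_mean(vals, pop, member)
            else:
                ok = member & np.isfinite(vals)
                if not ok.any():
                    raise ValueError(f"region {r} fully masked in {yr}")
                m = float(vals[ok].mean())
            rows.append({"region": int(r), "year": yr, "pw_mean": m})
    return pd.DataFrame(rows)


def national_series(
    annual: xr.DataArray,
    population: xr.DataArray | np.ndarray,
) -> pd.Series:
    """Nation-wide population-weighted mean EC per year."""
    pop = np.asarray(population, dtype=float)
    years = [int(y) for y in np.atleast_1d(annual.coords["year"].values)]
    return pd.Series(
        {yr: population_weighted_mean(annual.sel(year=yr).values, pop) for yr in years},
        name="pw_mean",
    )


def regional_trends(series: pd.DataFrame) -> pd.DataFrame:
    """Fit a linear trend per region from a regional_series frame."""
    rows = []
    for r, g in series.groupby("region"):
        tr = linear_trend(pd.Series(g["pw_mean"].to_numpy(), index=g["year"].to_numpy()))
        rows.append({"region": int(r), "slope": tr.slope,
                     "pct_change": tr.pct_change, "pct_change_raw": tr.pct_change_raw})
    return pd.DataFrame(rows)
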