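"""Readers and writers for the pipeline's on-disk formats.

Gridded fields travel as NetCDF (classic format via the scipy backend)
with CF-like attributes; monitors, demographics, regional series and
burden tables as CSV; the region partition as a cell-to-region CSV
plus a GeoJSON of dissolved region polygons.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grid import GridDefinition

_TIME_ENCODING = {"dtype": "float64", "units": "days since 2000-01-01"}


def write_dataarray(da: xr.DataArray, path: str | Path) -> Path:
    """Write one gridded field as a classic-format NetCDF file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = da.name or "field"
    ds = da.to_dataset(name=name)
    enc = {"time": _TIME_ENCODING} if "time" in ds.coords else {}
    # Classic NetCDF has no int64: keep attrs as str/float.
    for k, v in list(ds[name].attrs.items()):
        if isinstance(v, (np.integer, int)) and not isinstance(v, bool):
            ds[name].attrs[k] = float(v)
    ds.to_netcdf(path, engine="scipy", encoding=enc)
    return path


def read_dataarray(path: str | Path, name: str | None = None) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        if name is None:
            name = next(iter(ds.data_vars))
        da = ds[name].load()
    if "time" in da.coords:
        da = da.assign_coords(time=pd.DatetimeIndex(da.coords["time"].values))
    return da


def write_predictor_dir(fields: Mapping[str, xr.DataArray], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_dataarray(da, out_dir / f"{name}.nc") for name, da in fields.items()]


def read_predictor_dir(in_dir: str | Path) -> dict[str, xr.DataArray]:
    in_dir = Path(in_dir)
    out = {}
    for path in sorted(in_dir.glob("*.nc")):
        da = read_dataarray(path)
        out[path.stem] = da.rename(path.stem)
    if not out:
        raise FileNotFoundError(f"no .nc predictor files found in {in_dir}")
    return out


def write_region_map_csv(grid: GridDefinition, path: str | Path) -> Path:
    """Cell-to-region membership table (iy, ix, x_km, y_km, region)."""
    if grid.region_of is None:
        raise ValueError("grid has no region partition")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iy, ix = np.divmod(np.arange(grid.n_cells), grid.nx)
    pd.DataFrame({
        "iy": iy, "ix": ix,
        "x_km": grid.x_centers[ix], "y_km": grid.y_centers[iy],
        "region": grid.region_of[iy, ix],
    }).to_csv(path, index=False)
    return path


def read_region_map_csv(path: str | Path, grid: GridDefinition) -> np.ndarray:
    df = pd.read_csv(path)
    reg = np.full((grid.ny, grid.nx), -1, dtype=int)
    reg[df["iy"].to_numpy(), df["ix"].to_numpy()] = df["region"].to_numpy()
    if (reg < 0).any():
        raise ValueError(f"region map in {path} does not cover the grid")
    return reg


def write_regions_geojson(grid: GridDefinition, path: str | Path) -> Path:
    """Dissolved region polygons (planar km coordinates) as GeoJSON."""
    if grid.region_of is None:
        raise ValueError("grid has no region partition")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    xe, ye = grid.x_edges, grid.y_edges
    features = []
    for r in grid.region_ids:
        iy, ix = np.nonzero(grid.region_of == r)
        cells = [box(xe[j], ye[i], xe[j + 1], ye[i + 1]) for i, j in zip(iy, ix)]
        geom = unary_union(cells)
        features.append({
            "type": "Feature",
            "properties": {"region": int(r), "n_cells": int(len(cells))},
            "geometry": mapping(geom),
        })
    payload = {
        "type": "FeatureCollection",
        "crs_note": "planar kilometres, grid-local origin",
        "features": features,
    }
    path.write_text(json.dumps(payload))
    return path


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_monitors_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
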