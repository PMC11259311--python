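"""Analysis lattice and regridding operators.

The exposure model and the burden calculation both live on a single
regular planar grid (the "analysis grid", nominally 10 km cells).
Heterogeneous predictor products arrive on their own native lattices
and are brought onto the analysis grid either by area-weighted
averaging (gridded products) or by inverse-distance-weighted
interpolation (station-like point data).

All coordinates are planar kilometres; map projection handling is the
responsibility of whoever produces the native fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

AREAL_AVERAGE = "areal_average"
IDW = "idw"


@dataclass(frozen=True)
class GridDefinition:
    """A regular planar lattice of square cells plus a region partition.

    Parameters
    ----------
    nx, ny : int
        Number of cells along x and y.
    cell_size_km : float
        Side length of every (square) cell, in km.
    origin : (float, float)
        Planar coordinates of the lower-left corner of cell (0, 0).
    region_of : ndarray of shape (ny, nx), optional
        Integer region (province) id of every cell.  Every cell belongs
        to exactly one region.
    """

    nx: int
    ny: int
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    region_of: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be positive")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        if self.region_of is not None:
            reg = np.asarray(self.region_of, dtype=int)
            if reg.shape != (self.ny, self.nx):
                raise ValueError(
                    f"region_of has shape {reg.shape}, expected {(self.ny, self.nx)}"
                )
            if (reg < 0).any():
                raise ValueError("every cell must have a non-negative region id")
            object.__setattr__(self, "region_of", reg)

    # -- geometry -----------------------------------------------------
    @property
    def x_edges(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.nx + 1) * self.cell_size_km

    @property
    def y_edges(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.ny + 1) * self.cell_size_km

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell_size_km

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell_size_km

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded domain."""
        return (
            self.origin[0],
            self.origin[1],
            self.origin[0] + self.nx * self.cell_size_km,
            self.origin[1] + self.ny * self.cell_size_km,
        )

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) cell centers, row-major (iy, ix)."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return (x0 <= x <= x1) and (y0 <= y <= y1)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(iy, ix) of the cell containing planar point (x, y)."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) lies outside grid bounds {self.bounds}")
        ix = min(int((x - self.origin[0]) // self.cell_size_km), self.nx - 1)
        iy = min(int((y - self.origin[1]) // self.cell_size_km), self.ny - 1)
        return iy, ix

    @property
    def region_ids(self) -> np.ndarray:
        if self.region_of is None:
            raise ValueError("grid has no region partition")
        return np.unique(self.region_of)

    def coords(self) -> dict[str, np.ndarray]:
        return {"y": self.y_centers, "x": self.x_centers}


@dataclass
class RegriddedField:
    """A predictor brought onto the analysis grid.

    ``values`` is an xarray.DataArray with dims (..., 'y', 'x') on the
    target grid coordinates; NaN marks invalid cells.  ``method`` is the
    regridding operator used ('areal_average' or 'idw').
    """

    name: str
    values: xr.DataArray
    method: str

    @property
    def mask(self) -> np.ndarray:
        """Validity flags (True where the value is usable)."""
        return np.isfinite(self.values.values)


def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    if centers.size == 1:
        # Single-cell axis: width must come from attrs; fall back to 1.
        raise ValueError("cannot infer edges from a single center without spacing")
    d = np.diff(centers)
    if not np.allclose(d, d[0]):
        raise ValueError("non-uniform source lattice")
    step = d[0]
    return np.concatenate([[centers[0] - step / 2], centers + step / 2])


def _axis_edges(da: xr.DataArray, axis: str) -> np.ndarray:
    centers = np.asarray(da.coords[axis].values, dtype=float)
    if centers.size == 1:
        step = float(da.attrs.get("native_cell_km", 0.0))
        if step <= 0:
            raise ValueError(
                f"single-cell axis {axis!r} needs a 'native_cell_km' attribute"
            )
        return np.array([centers[0] - step / 2, centers[0] + step / 2])
    return _edges_from_centers(centers)


def _overlap_matrix(tgt_edges: np.ndarray, src_edges: np.ndarray) -> np.ndarray:
    """Pairwise 1-D overlap lengths between target and source intervals."""
    lo = np.maximum(tgt_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(tgt_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def areal_average(source: xr.DataArray, target: GridDefinition) -> RegriddedField:
    """Area-weighted average of a native gridded field onto the target grid.

    Each target cell receives the overlap-area-weighted mean of the
    valid source cells it intersects; target cells with no valid
    overlapping source area are masked (NaN).  Works on (y, x) and
    (time, y, x) arrays alike.
    """
    sx_edges = _axis_edges(source, "x")
    sy_edges = _axis_edges(source, "y")
    tx_edges, ty_edges = target.x_edges, target.y_edges

    if sx_edges[-1] <= tx_edges[0] or sx_edges[0] >= tx_edges[-1] or \
       sy_edges[-1] <= ty_edges[0] or sy_edges[0] >= ty_edges[-1]:
        src_box = (sx_edges[0], sy_edges[0], sx_edges[-1], sy_edges[-1])
        raise ValueError(
            f"source extent {src_box} is disjoint from target extent {target.bounds}"
        )

    wx = _overlap_matrix(tx_edges, sx_edges)  # (nx_t, nx_s)
    wy = _overlap_matrix(ty_edges, sy_edges)  # (ny_t, ny_s)

    v = np.asarray(source.values, dtype=float)
    valid = np.isfinite(v)
    v_filled = np.where(valid, v, 0.0)

    # out[..., i, j] = sum_{b,c} wy[i,b] v[..., b,c] wx[j,c]
    num = np.einsum("ib,...bc,jc->...ij", wy, v_filled, wx)
    den = np.einsum("ib,...bc,jc->...ij", wy, valid.astype(float), wx)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    dims = list(source.dims[:-2]) + ["y", "x"]
    coords = {k: source.coords[k] for k in source.dims[:-2] if k in source.coords}
    coords.update(target.coords())
    da = xr.DataArray(out, dims=dims, coords=coords, name=source.name, attrs=dict(source.attrs))
    da.attrs["regrid_method"] = AREAL_AVERAGE
    return RegriddedField(name=str(source.name), values=da, method=AREAL_AVERAGE)


class IDWInterpolator(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighted interpolation as a fit/predict estimator.

    Prediction at a query point is the weighted mean of the values at
    its ``k_neighbors`` nearest fitted points, with weights d^(-power).
    A query point within ``snap_tol`` of a fitted point returns that
    point's value exactly.

    Parameters
    ----------
    power : float, default 2.0
        Distance exponent (> 0).
    k_neighbors : int, default 8
        Neighbourhood size; capped at the number of fitted points.
    snap_tol : float, default 1e-12
        Distance below which a query is treated as coincident with a
        data point.
    """

    def __init__(self, power: float = 2.0, k_neighbors: int = 8, snap_tol: float = 1e-12):
        self.power = power
        self.k_neighbors = k_neighbors
        self.snap_tol = snap_tol

    def fit(self, X, y):
        if not self.power > 0:
            raise ValueError("power must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        X, y = check_X_y(X, y, ensure_min_samples=1)
        if X.shape[1] != 2:
            raise ValueError("expected planar (x, y) coordinates")
        self.X_ = X
        self.y_ = y
        self.tree_ = cKDTree(X)
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = check_array(X)
        k = min(self.k_neighbors, len(self.y_))
        d, idx = self.tree_.query(X, k=k)
        d = np.atleast_2d(d.reshape(len(X), k))
        idx = np.atleast_2d(idx.reshape(len(X), k))
        vals = self.y_[idx]
        snapped = d[:, 0] < self.snap_tol
        with np.errstate(divide="ignore"):
            w = d ** (-self.power)
        w[~np.isfinite(w)] = 0.0
        out = np.einsum("ij,ij->i", w, vals) / np.maximum(w.sum(axis=1), np.finfo(float).tiny)
        out[snapped] = vals[snapped, 0]
        return out


def idw_interpolate(
    points: Sequence[tuple[float, float]] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    target: GridDefinition,
    power: float = 2.0,
    k_neighbors: int = 8,
    name: str = "field",
) -> RegriddedField:
    """IDW-interpolate scattered point values onto every target cell center.

    ``values`` may be (n_points,) for a single snapshot or
    (n_times, n_points) for a stack sharing the same station set
    (NaN station-days are dropped per time step).
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("at least one point is required")
    snap = 1e-9 * target.cell_size_km
    centers = target.cell_centers()

    def _one(v: np.ndarray) -> np.ndarray:
        ok = np.isfinite(v)
        if not ok.any():
            return np.full(target.n_cells, np.nan)
        est = IDWInterpolator(power=power, k_neighbors=k_neighbors, snap_tol=snap)
        est.fit(pts[ok], v[ok])
        return est.predict(centers)

    if vals.ndim == 1:
        out = _one(vals).reshape(target.ny, target.nx)
        da = xr.DataArray(out, dims=("y", "x"), coords=target.coords(), name=name)
    else:
        out = np.stack([_one(v) for v in vals]).reshape(-1, target.ny, target.nx)
        da = xr.DataArray(out, dims=("time", "y", "x"),
                          coords={**target.coords()}, name=name)
    da.attrs["regrid_method"] = IDW
    return RegriddedField(name=name, values=da, method=IDW)


def _idw_gridded(source: xr.DataArray, target: GridDefinition,
                 power: float, k_neighbors: int) -> RegriddedField:
    """Treat a native gridded field's cell centers as stations and IDW them."""
    xs = np.asarray(source.coords["x"].values, dtype=float)
    ys = np.asarray(source.coords["y"].values, dtype=float)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    if source.ndim == 2:
        fld = idw_interpolate(pts, source.values.ravel(), target,
                              power=power, k_neighbors=k_neighbors, name=str(source.name))
        fld.values.attrs.update(source.attrs)
        fld.values.attrs["regrid_method"] = IDW
        return fld
    vals = source.values.reshape(source.shape[0], -1)
    fld = idw_interpolate(pts, vals, target, power=power,
                          k_neighbors=k_neighbors, name=str(source.name))
    fld.values = fld.values.assign_coords(time=("time", source.coords["time"].values))
    fld.values.attrs.update(source.attrs)
    fld.values.attrs["regrid_method"] = IDW
    return fld


# Default operator per predictor family: gridded products are areally
# averaged; station-like visibility is IDW-interpolated.
DEFAULT_REGRID_METHODS: dict[str, str] = {"visibility": IDW}


def regrid_stack(
    native: Mapping[str, xr.DataArray],
    target: GridDefinition,
    methods: Mapping[str, str] | None = None,
    idw_power: float = 2.0,
    idw_k_neighbors: int = 8,
) -> dict[str, RegriddedField]:
    """Bring every native predictor field onto the analysis grid."""
    chosen = dict(DEFAULT_REGRID_METHODS)
    if methods:
        chosen.update(methods)
    out: dict[str, RegriddedField] = {}
    for name, da in native.items():
        method = chosen.get(name, AREAL_AVERAGE)
        if method == IDW:
            out[name] = _idw_gridded(da, target, idw_power, idw_k_neighbors)
        elif method == AREAL_AVERAGE:
            out[name] = areal_average(da, target)
        else:
            raise ValueError(f"unknown regrid method {method!r} for {name!r}")
    return out


def expand_daily(da: xr.DataArray, dates: pd.DatetimeIndex) -> xr.DataArray:
    """Expand a static/monthly/daily field to one slice per requested day.

    The field's ``temporal`` attribute ('static', 'monthly' or 'daily')
    governs the expansion; daily fields must already cover the dates.
    """
    temporal = da.attrs.get("temporal", "daily" if "time" in da.dims else "static")
    if temporal == "static":
        vals = np.broadcast_to(da.values, (len(dates),) + da.shape).copy()
    elif temporal == "daily":
        t = pd.DatetimeIndex(da.coords["time"].values)
        pos = t.get_indexer(dates)
        if (pos < 0).any():
            raise ValueError(f"daily field {da.name!r} does not cover all requested dates")
        vals = da.values[pos]
    elif temporal == "monthly":
        t = pd.DatetimeIndex(da.coords["time"].values)
        key = t.year * 12 + t.month
        want = dates.year * 12 + dates.month
        lookup = {k: i for i, k in enumerate(key)}
        try:
            pos = np.array([lookup[w] for w in want])
        except KeyError as exc:
            raise ValueError(f"monthly field {da.name!r} missing month {exc}") from exc
        vals = da.values[pos]
    else:
        raise ValueError(f"unknown temporal kind {temporal!r}")
    out = xr.DataArray(
        vals,
        dims=("time", "y", "x"),
        coords={"time": dates, "y": da.coords["y"], "x": da.coords["x"]},
        name=da.name,
        attrs=dict(da.attrs),
    )
    out.attrs["temporal"] = "daily"
    return out
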