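"""Daily EC exposure model: bagged regression trees with OOB evaluation.

The model regresses daily ground EC observations on the 13 regridded
predictors at the monitor's grid cell, using a random forest whose
performance is evaluated out-of-bag (each observation scored only by
trees whose bootstrap sample excluded it).  Predictors are ranked by
permutation feature importance: the increase in prediction error (and
decrease in R^2) when one predictor's column is shuffled while the
others are left unchanged.

Two R^2 conventions exist in the validation literature; both are
computed.  The headline ``oob_r2_`` is the squared Pearson correlation
between OOB predictions and observations (matching the usual
observed-vs-predicted regression presentation); ``oob_r2_score_`` is
the 1 - SSE/SST variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.utils.validation import check_is_fitted

from .grid import GridDefinition, RegriddedField, expand_daily
from .synth import PREDICTOR_NAMES

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingTable:
    """Site-day rows with complete observations and predictors.

    ``frame`` columns: site_id, date, ec_obs, then one column per
    predictor.  ``dropped`` counts discarded rows by cause (missing
    observation, missing predictor by name).
    """

    frame: pd.DataFrame
    dropped: dict[str, int]

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c in PREDICTOR_NAMES]

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        return self.frame["ec_obs"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class EvaluationReport:
    """Observed-vs-predicted regression summary at one temporal level."""

    level: str   # 'daily' | 'monthly'
    r2: float    # squared Pearson correlation
    slope: float
    intercept: float
    n: int
    rmse: float


def build_training_table(
    monitors: pd.DataFrame,
    sites: pd.DataFrame,
    gridded: Mapping[str, RegriddedField] | Mapping[str, xr.DataArray],
    grid: GridDefinition,
) -> TrainingTable:
    """Join monitor observations with the regridded predictors.

    One row per site-day with a valid observation and all 13 predictors
    present; every dropped row is counted by cause.  Sites must lie
    inside the grid.
    """
    for _, s in sites.iterrows():
        if not grid.contains(float(s["x_km"]), float(s["y_km"])):
            raise ValueError(
                f"site {s['site_id']} at ({s['x_km']}, {s['y_km']}) lies outside "
                f"grid bounds {grid.bounds}"
            )
    df = monitors.merge(sites[["site_id", "ix", "iy"]], on="site_id", how="left", validate="m:1")
    if df["ix"].isna().any():
        missing = sorted(set(df.loc[df["ix"].isna(), "site_id"]))
        raise ValueError(f"monitor records reference unknown site(s): {missing}")

    dropped: dict[str, int] = {}
    n_obs_missing = int(df["ec_obs"].isna().sum())
    if n_obs_missing:
        dropped["missing_observation"] = n_obs_missing
        df = df.dropna(subset=["ec_obs"])

    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    arrays = {}
    for name in PREDICTOR_NAMES:
        if name not in gridded:
            raise KeyError(f"missing regridded predictor {name!r}")
        da = gridded[name]
        da = da.values if isinstance(da, RegriddedField) else da
        arrays[name] = expand_daily(da, dates)

    t_pos = dates.get_indexer(pd.DatetimeIndex(df["date"]))
    iy = df["iy"].to_numpy(dtype=int)
    ix = df["ix"].to_numpy(dtype=int)
    for name, da in arrays.items():
        df[name] = da.values[t_pos, iy, ix]

    keep = np.ones(len(df), dtype=bool)
    for name in PREDICTOR_NAMES:
        bad = df[name].isna().to_numpy() & keep
        if bad.any():
            dropped[f"missing_{name}"] = int(bad.sum())
            keep &= ~bad
    df = df.loc[keep].reset_index(drop=True)

    if len(df) == 0:
        raise ValueError("no usable training rows after dropping incomplete site-days")
    if dropped:
        logger.info("training table: dropped rows by cause: %s", dropped)
    cols = ["site_id", "date", "ec_obs", *PREDICTOR_NAMES]
    return TrainingTable(frame=df[cols], dropped=dropped)


class ExposureRandomForest(RegressorMixin, BaseEstimator):
    """Random-forest EC regressor with out-of-bag evaluation.

    Parameters
    ----------
    n_trees : int, default 500
        Ensemble size.
    max_features : float, default 1/3
        Fraction of predictors considered per split (the p/3
        regression-forest convention).
    max_depth : int or None, default None
        Unlimited depth by default.
    min_rows : int, default 50
        Minimum training-table size accepted.
    seed : int, default 0
        Controls bootstrap resampling and split randomness.

    Fitted attributes
    -----------------
    forest_ : the underlying fitted ensemble
    oob_prediction_ : per-row OOB predictions
    oob_r2_ : squared Pearson correlation of OOB predictions vs observations
    oob_r2_score_ : the 1 - SSE/SST variant
    oob_rmse_ : OOB root-mean-square error (ug m-3)
    training_meta_ : dict with n_rows, n_trees, seed
    """

    def __init__(self, n_trees: int = 500, max_features: float = 1.0 / 3.0,
                 max_depth: int | None = None, min_samples_leaf: int = 1,
                 min_rows: int = 50, seed: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.min_rows = min_rows
        self.seed = seed

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if len(y) < self.min_rows:
            raise ValueError(f"need at least {self.min_rows} training rows, got {len(y)}")
        if np.unique(y).size < 2:
            raise ValueError("degenerate training table: constant response")
        self.n_features_in_ = X.shape[1]
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        oob = np.asarray(self.forest_.oob_prediction_, dtype=float)
        self.oob_prediction_ = oob
        self.y_train_ = y
        self.oob_r2_ = float(np.corrcoef(oob, y)[0, 1] ** 2)
        self.oob_r2_score_ = float(self.forest_.oob_score_)
        self.oob_rmse_ = float(np.sqrt(np.mean((oob - y) ** 2)))
        self.training_meta_ = {"n_rows": int(len(y)), "n_trees": int(self.n_trees),
                               "seed": int(self.seed)}
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.forest_.predict(X)

    def inbag_counts(self) -> np.ndarray:
        """(n_trees, n_rows) bootstrap inclusion counts, for OOB auditing."""
        check_is_fitted(self, "forest_")
        from sklearn.ensemble._forest import (_generate_sample_indices,
                                              _get_n_samples_bootstrap)
        n = len(self.y_train_)
        n_boot = _get_n_samples_bootstrap(n, self.forest_.max_samples, None)
        counts = np.zeros((len(self.forest_.estimators_), n), dtype=int)
        for t, tree in enumerate(self.forest_.estimators_):
            idx = _generate_sample_indices(tree.random_state, n, n_boot, None)
            np.add.at(counts[t], idx, 1)
        return counts


def fit_exposure_model(table: TrainingTable, n_trees: int = 500, seed: int = 0,
                       **kwargs) -> ExposureRandomForest:
    """Fit the exposure forest on a training table."""
    model = ExposureRandomForest(n_trees=n_trees, seed=seed, **kwargs)
    return model.fit(table.X, table.y)


def permutation_importance(
    model: ExposureRandomForest,
    table: TrainingTable,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank predictors by the damage done when each is permuted.

    Returns a DataFrame indexed by predictor, sorted by descending
    ``rmse_increase``, with the R^2 decrease, per-repeat standard
    deviations and a share normalized over positive error increases.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if len(table) == 0:
        raise ValueError("empty table")
    check_is_fitted(model, "forest_")
    res = _sk_permutation_importance(
        model, table.X, table.y,
        scoring={"rmse": "neg_root_mean_squared_error", "r2": "r2"},
        n_repeats=n_repeats, random_state=seed, n_jobs=1,
    )
    out = pd.DataFrame({
        "predictor": table.feature_names,
        "rmse_increase": res["rmse"].importances_mean,
        "rmse_increase_sd": res["rmse"].importances_std,
        "r2_decrease": res["r2"].importances_mean,
        "r2_decrease_sd": res["r2"].importances_std,
    }).set_index("predictor")
    pos = np.clip(out["rmse_increase"].to_numpy(), 0.0, None)
    total = pos.sum()
    out["share"] = pos / total if total > 0 else 0.0
    return out.sort_values("rmse_increase", ascending=False)


def predict_daily_surface(
    model: ExposureRandomForest,
    gridded: Mapping[str, RegriddedField] | Mapping[str, xr.DataArray],
    grid: GridDefinition,
    dates: pd.DatetimeIndex | None = None,
    chunk_rows: int = 200_000,
) -> xr.DataArray:
    """Predict daily EC on every grid cell with complete predictors.

    Cells missing any predictor on a day are flagged missing (NaN),
    never zero-filled.  Returns a (time, y, x) DataArray in ug m-3.
    """
    arrays = {}
    for name in PREDICTOR_NAMES:
        if name not in gridded:
            raise KeyError(f"missing predictor field {name!r}")
        da = gridded[name]
        da = da.values if isinstance(da, RegriddedField) else da
        arrays[name] = da
    if dates is None:
        times = [pd.DatetimeIndex(a.coords["time"].values)
                 for a in arrays.values()
                 if a.attrs.get("temporal", "static") == "daily" and "time" in a.dims]
        if not times:
            raise ValueError("no daily predictor to infer dates from; pass dates=")
        dates = times[0]
    expanded = np.stack(
        [expand_daily(arrays[name], dates).values.reshape(len(dates), -1)
         for name in PREDICTOR_NAMES], axis=-1,
    )  # (time, cell, predictor)
    nt, nc, npred = expanded.shape
    flat = expanded.reshape(nt * nc, npred)
    ok = np.isfinite(flat).all(axis=1)
    pred = np.full(nt * nc, np.nan)
    idx = np.nonzero(ok)[0]
    for start in range(0, len(idx), chunk_rows):
        sel = idx[start:start + chunk_rows]
        pred[sel] = model.predict(flat[sel])
    out = xr.DataArray(
        pred.reshape(nt, grid.ny, grid.nx),
        dims=("time", "y", "x"),
        coords={"time": dates, **grid.coords()},
        name="ec_pred", attrs={"units": "ug m-3"},
    )
    n_masked = int((~ok).sum())
    if n_masked:
        logger.info("prediction surface: %d of %d cell-days masked (incomplete predictors)",
                    n_masked, nt * nc)
    return out


def evaluate(
    model: ExposureRandomForest,
    table: TrainingTable,
    level: str = "daily",
    min_monthly_obs: int = 8,
    predictions: np.ndarray | None = None,
) -> EvaluationReport:
    """Observed-vs-predicted regression at the daily or monthly level.

    By default the model's OOB predictions are used (the table must be
    the one the model was fitted on); pass ``predictions`` to evaluate
    any other prediction vector.  Monthly evaluation keeps only
    site-months with at least ``min_monthly_obs`` daily observations
    (the strict reading of "more than seven" being >= 8).
    """
    if level not in ("daily", "monthly"):
        raise ValueError("level must be 'daily' or 'monthly'")
    if predictions is None:
        check_is_fitted(model, "oob_prediction_")
        if len(table) != len(model.oob_prediction_):
            raise ValueError(
                "table size does not match the fitted model's training table; "
                "pass explicit predictions= to evaluate other data"
            )
        predictions = model.oob_prediction_
    obs = table.y
    pred = np.asarray(predictions, dtype=float)

    if level == "monthly":
        df = pd.DataFrame({
            "site_id": table.frame["site_id"],
            "period": pd.DatetimeIndex(table.frame["date"]).to_period("M"),
            "obs": obs, "pred": pred,
        })
        g = df.groupby(["site_id", "period"], observed=True).agg(
            n=("obs", "size"), obs=("obs", "mean"), pred=("pred", "mean"))
        g = g[g["n"] >= min_monthly_obs]
        if len(g) == 0:
            raise ValueError(
                f"no site-months with >= {min_monthly_obs} daily observations")
        obs, pred = g["obs"].to_numpy(), g["pred"].to_numpy()

    fit = stats.linregress(pred, obs)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return EvaluationReport(level=level, r2=float(fit.rvalue**2),
                            slope=float(fit.slope), intercept=float(fit.intercept),
                            n=int(len(obs)), rmse=rmse)


def save_model(model: ExposureRandomForest, path) -> None:
    """Serialize a fitted model to a single versioned file."""
    check_is_fitted(model, "forest_")
    joblib.dump({"format": "ecburden-exposure-model",
                 "format_version": MODEL_FORMAT_VERSION,
                 "model": model}, path)


def load_model(path) -> ExposureRandomForest:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "ecburden-exposure-model":
        raise ValueError(f"{path} is not an ecburden exposure-model file")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')}")
    return payload["model"]
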