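"""Exposure forest: training table, OOB discipline, importance, prediction."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from ecburden.expomodel import (ExposureRandomForest, TrainingTable,
                                build_training_table, evaluate,
                                fit_exposure_model, permutation_importance,
                                predict_daily_surface)
from ecburden.grid import GridDefinition
from ecburden.synth import PREDICTOR_NAMES, SynthConfig, simulate

from .conftest import make_source


def toy_world(n_days=10, n_sites=3, nx=4, ny=4):
    """Hand-built grid, static predictor stack and complete monitors."""
    grid = GridDefinition(nx=nx, ny=ny, cell_size_km=10.0)
    rng = np.random.default_rng(0)
    gridded = {}
    for i, name in enumerate(PREDICTOR_NAMES):
        da = make_source(rng.random((ny, nx)) + i, 10.0, name=name)
        da.attrs["temporal"] = "static"
        gridded[name] = da
    dates = pd.date_range("2013-01-01", periods=n_days)
    iy = np.arange(n_sites) % ny
    ix = (np.arange(n_sites) * 2 + 1) % nx
    sites = pd.DataFrame({
        "site_id": [f"S{i}" for i in range(n_sites)],
        "ix": ix, "iy": iy,
        "x_km": grid.x_centers[ix], "y_km": grid.y_centers[iy],
    })
    monitors = pd.DataFrame([
        {"site_id": s, "date": d, "ec_obs": 2.0 + 0.1 * k}
        for k, (s, d) in enumerate((s, d) for s in sites["site_id"] for d in dates)
    ])
    return grid, gridded, sites, monitors, dates


class TestTrainingTable:
    def test_complete_data_row_count(self):
        grid, gridded, sites, monitors, _ = toy_world()
        table = build_training_table(monitors, sites, gridded, grid)
        assert len(table) == 30
        assert table.dropped == {}
        assert list(table.feature_names) == list(PREDICTOR_NAMES)

    def test_missing_predictor_drops_and_logs(self):
        grid, gridded, sites, monitors, dates = toy_world()
        # Break ndvi at site S0's cell: static field -> all 10 of its days drop.
        da = gridded["ndvi"].copy(deep=True)
        da.values[0, 1] = np.nan
        da.attrs["temporal"] = "static"
        gridded["ndvi"] = da
        table = build_training_table(monitors, sites, gridded, grid)
        assert len(table) == 20
        assert table.dropped == {"missing_ndvi": 10}

    def test_missing_observation_dropped(self):
        grid, gridded, sites, monitors, _ = toy_world()
        monitors.loc[0, "ec_obs"] = np.nan
        table = build_training_table(monitors, sites, gridded, grid)
        assert len(table) == 29
        assert table.dropped == {"missing_observation": 1}

    def test_site_outside_grid_rejected(self):
        grid, gridded, sites, monitors, _ = toy_world()
        sites.loc[0, "x_km"] = 1e6
        with pytest.raises(ValueError, match="outside"):
            build_training_table(monitors, sites, gridded, grid)

    def test_all_rows_dropped_is_an_error(self):
        grid, gridded, sites, monitors, _ = toy_world()
        monitors["ec_obs"] = np.nan
        with pytest.raises(ValueError, match="no usable"):
            build_training_table(monitors, sites, gridded, grid)


class TestFit:
    def test_too_few_rows_rejected(self):
        X = np.random.default_rng(0).random((20, 13))
        y = np.arange(20.0)
        with pytest.raises(ValueError, match="at least"):
            ExposureRandomForest(n_trees=10).fit(X, y)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).random((60, 13))
        with pytest.raises(ValueError, match="constant"):
            ExposureRandomForest(n_trees=10).fit(X, np.ones(60))

    def test_deterministic_given_seed(self, small_table):
        a = fit_exposure_model(small_table, n_trees=50, seed=3)
        b = fit_exposure_model(small_table, n_trees=50, seed=3)
        np.testing.assert_array_equal(a.oob_prediction_, b.oob_prediction_)
        assert a.oob_r2_ == b.oob_r2_

    def test_oob_discipline(self, small_table):
        # No in-bag observation contributes to its own OOB prediction:
        # recompute OOB predictions from the bag-membership hook and
        # require equality with the model's own.
        model = fit_exposure_model(small_table, n_trees=60, seed=1)
        counts = model.inbag_counts()
        X = small_table.X.to_numpy(dtype=float)
        per_tree = np.stack([t.predict(X) for t in model.forest_.estimators_])
        oob_mask = counts == 0
        manual = (per_tree * oob_mask).sum(axis=0) / oob_mask.sum(axis=0)
        np.testing.assert_allclose(manual, model.oob_prediction_, rtol=1e-10)

    def test_null_model_after_response_permutation(self, small_table):
        rng = np.random.default_rng(0)
        frame = small_table.frame.copy()
        frame["ec_obs"] = rng.permutation(frame["ec_obs"].to_numpy())
        null = fit_exposure_model(TrainingTable(frame, {}), n_trees=100, seed=0)
        assert null.oob_r2_ <= 0.05

    def test_prediction_bounded_by_training_range(self, small_model, small_table):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 100, size=(200, 13))  # far outside training support
        pred = small_model.predict(X)
        y = small_table.y
        assert pred.min() >= y.min() - 1e-12
        assert pred.max() <= y.max() + 1e-12


class TestImportance:
    def test_zero_repeats_rejected(self, small_model, small_table):
        with pytest.raises(ValueError, match="n_repeats"):
            permutation_importance(small_model, small_table, n_repeats=0)

    def test_covers_all_predictors_sorted(self, small_model, small_table):
        imp = permutation_importance(small_model, small_table, n_repeats=3, seed=0)
        assert set(imp.index) == set(PREDICTOR_NAMES)
        assert (np.diff(imp["rmse_increase"].to_numpy()) <= 1e-12).all()
        assert imp["share"].sum() == pytest.approx(1.0)

    def test_single_driver_ranks_first(self):
        cfg = SynthConfig(grid_nx=10, grid_ny=10, years=(2013,), n_sites=8,
                          n_regions=3, seed=21, noise_sd=0.0, obs_noise_sd=0.0,
                          seasonal_amplitude=0.0, emission_trend_per_year=0.0,
                          true_coefficients={"road_length": 2.0})
        b = simulate(cfg)
        table = build_training_table(b.monitors, b.sites, b.gridded, b.grid)
        model = fit_exposure_model(table, n_trees=100, seed=21, max_features=1.0)
        imp = permutation_importance(model, table, n_repeats=3, seed=21)
        assert imp.index[0] == "road_length"


class TestPredictSurface:
    def test_constant_predictors_give_constant_surface(self):
        grid, gridded, sites, monitors, dates = toy_world()
        for name in gridded:
            gridded[name] = gridded[name].copy(deep=True)
            gridded[name].values[:] = float(len(name))  # distinct constants
            gridded[name].attrs["temporal"] = "static"
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((60, 13)), columns=list(PREDICTOR_NAMES))
        model = ExposureRandomForest(n_trees=20, seed=0).fit(X, rng.random(60))
        surf = predict_daily_surface(model, gridded, grid, dates=dates)
        assert float(surf.std()) == pytest.approx(0.0, abs=1e-12)

    def test_missing_predictor_named_in_error(self, small_model, small_bundle):
        gridded = dict(small_bundle.gridded)
        gridded.pop("pblh")
        with pytest.raises(KeyError, match="pblh"):
            predict_daily_surface(small_model, gridded, small_bundle.grid)

    def test_gap_cells_flagged_missing_never_zero_filled(self):
        cfg = SynthConfig(grid_nx=8, grid_ny=8, years=(2013,), n_sites=6,
                          n_regions=3, seed=7,
                          swath_gap=(0.0, 0.5, 0.0, 0.5), swath_gap_period=2)
        b = simulate(cfg)
        table = build_training_table(b.monitors, b.sites, b.gridded, b.grid)
        model = fit_exposure_model(table, n_trees=30, seed=7)
        surf = predict_daily_surface(model, b.gridded, b.grid, dates=cfg.dates())
        assert np.isnan(surf.values[0, 0, 0])       # gap day, gap cell
        assert np.isfinite(surf.values[1, 0, 0])    # off-gap day
        assert not (surf.values == 0.0).any()


class TestEvaluate:
    def _table(self, counts_by_month):
        rows = []
        rng = np.random.default_rng(0)
        for (year, month), n in counts_by_month.items():
            for d in range(n):
                rows.append({"site_id": "S0",
                             "date": pd.Timestamp(year, month, d + 1),
                             "ec_obs": float(rng.normal(3, 1))})
        frame = pd.DataFrame(rows)
        for name in PREDICTOR_NAMES:
            frame[name] = 0.0
        return TrainingTable(frame, {})

    def test_identity_predictions(self):
        table = self._table({(2013, 1): 20, (2013, 2): 20})
        pred = table.y.copy()
        rep = evaluate(ExposureRandomForest(), table, "daily", predictions=pred)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)
        assert rep.n == 40

    def test_monthly_rule_excludes_seven_includes_eight(self):
        # "More than seven daily observations" read strictly: a
        # site-month with exactly 7 days is out, with 8 it is in.
        table = self._table({(2013, 1): 7, (2013, 2): 8, (2013, 3): 12})
        pred = table.y + np.random.default_rng(1).normal(0, 0.1, len(table))
        rep = evaluate(ExposureRandomForest(), table, "monthly", predictions=pred)
        assert rep.n == 2  # February and March only

    def test_no_qualifying_months_is_an_error(self):
        table = self._table({(2013, 1): 5, (2013, 2): 6})
        with pytest.raises(ValueError, match="site-months"):
            evaluate(ExposureRandomForest(), table, "monthly", predictions=table.y)

    def test_invalid_level_rejected(self, small_model, small_table):
        with pytest.raises(ValueError, match="level"):
            evaluate(small_model, small_table, "weekly")

    def test_monthly_averaging_improves_fit(self):
        # Monthly means average out observation noise: over 5 seeds the
        # monthly R^2 should not fall below the daily R^2 (one-sided
        # tolerance for Monte-Carlo wiggle).
        daily_r2, monthly_r2 = [], []
        for seed in range(5):
            cfg = SynthConfig(grid_nx=8, grid_ny=8, years=(2013,), n_sites=8,
                              n_regions=3, seed=seed, obs_missing_rate=0.1)
            b = simulate(cfg)
            table = build_training_table(b.monitors, b.sites, b.gridded, b.grid)
            m = fit_exposure_model(table, n_trees=80, seed=seed)
            daily_r2.append(evaluate(m, table, "daily").r2)
            monthly_r2.append(evaluate(m, table, "monthly").r2)
        assert np.mean(monthly_r2) >= np.mean(daily_r2) - 0.02


class TestSerialization:
    def test_roundtrip_and_header_check(self, small_model, small_table, tmp_path):
        from ecburden.expomodel import load_model, save_model
        path = tmp_path / "model.joblib"
        save_model(small_model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict(small_table.X.iloc[:5]),
                                      small_model.predict(small_table.X.iloc[:5]))
        import joblib
        joblib.dump({"format": "something-else"}, tmp_path / "bad.joblib")
        with pytest.raises(ValueError, match="not an ecburden"):
            load_model(tmp_path / "bad.joblib")
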