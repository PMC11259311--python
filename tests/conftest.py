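import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import HealthCheck, settings

from ecburden.expomodel import build_training_table, fit_exposure_model
from ecburden.grid import GridDefinition
from ecburden.synth import SynthConfig, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Desk-scale world: 8x8 grid, one year, 6 sites, 3 regions."""
    return SynthConfig(grid_nx=8, grid_ny=8, years=(2013,), n_sites=6,
                       n_regions=3, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def small_table(small_bundle):
    return build_training_table(small_bundle.monitors, small_bundle.sites,
                                small_bundle.gridded, small_bundle.grid)


@pytest.fixture(scope="session")
def small_model(small_table):
    return fit_exposure_model(small_table, n_trees=100, seed=7)


@pytest.fixture
def grid6() -> GridDefinition:
    return GridDefinition(nx=6, ny=6, cell_size_km=10.0)


def make_source(values: np.ndarray, cell_km: float, origin=(0.0, 0.0),
                name: str = "field", time=None) -> xr.DataArray:
    """Native-lattice DataArray helper for regridding tests."""
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape[-2:]
    ys = origin[1] + (np.arange(ny) + 0.5) * cell_km
    xs = origin[0] + (np.arange(nx) + 0.5) * cell_km
    if time is None:
        da = xr.DataArray(values, dims=("y", "x"), coords={"y": ys, "x": xs}, name=name)
    else:
        da = xr.DataArray(values, dims=("time", "y", "x"),
                          coords={"time": pd.DatetimeIndex(time), "y": ys, "x": xs},
                          name=name)
    da.attrs["native_cell_km"] = cell_km
    return da
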