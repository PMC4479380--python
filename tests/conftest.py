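import numpy as np
import pandas as pd
import pytest

from weathersdm import ClimateCube, SyntheticConfig, gen_weather, truth_surface


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cube(n_years=4, ny=3, nx=3, start_year=1990, seed=0, constant=False):
    """Small hand-rolled cube: seasonal cycle + optional noise, valid ordering."""
    rng = np.random.default_rng(seed)
    T = 12 * n_years
    time = pd.period_range(f"{start_year}-01", periods=T, freq="M")
    month = time.month.to_numpy()
    season = -6.0 * np.cos(2 * np.pi * (month - 7) / 12.0)
    tmean = 10.0 + season[:, None, None] + np.zeros((T, ny, nx))
    precip = 60.0 + 30.0 * np.cos(2 * np.pi * (month - 7) / 12.0)
    precip = precip[:, None, None] + np.zeros((T, ny, nx))
    if not constant:
        tmean = tmean + rng.normal(0, 0.5, (T, ny, nx))
        precip = np.clip(precip + rng.normal(0, 5.0, (T, ny, nx)), 0, None)
    return ClimateCube(
        time=time,
        y=np.arange(ny, dtype=float) * 5.0,
        x=np.arange(nx, dtype=float) * 5.0,
        precip=precip,
        tmin=tmean - 5.0,
        tmax=tmean + 5.0,
        tmean=tmean,
    )


@pytest.fixture
def small_cube():
    return make_cube()


@pytest.fixture(scope="session")
def island():
    """A moderate synthetic island with weather, truth, shared across tests."""
    config = SyntheticConfig(
        grid_rows=12, grid_cols=12, start_year=1985, end_year=2009, seed=7
    )
    cube = gen_weather(config)
    truth = truth_surface(cube, window_length=36)
    return config, cube, truth
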