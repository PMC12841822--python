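import numpy as np
import pytest

import pestcast as pc
from pestcast.engine import prepare_engine_inputs


@pytest.fixture(scope="session")
def small_spec():
    return pc.SyntheticWorldSpec(nlat=30, nlon=60, seed=42)


@pytest.fixture(scope="session")
def small_climate(small_spec):
    return pc.make_synthetic_climate(small_spec)


@pytest.fixture(scope="session")
def small_bioclim(small_climate):
    return pc.compute_bioclim(small_climate)


@pytest.fixture(scope="session")
def world_spec():
    """The default 2-degree synthetic world used by the heavier experiments."""
    return pc.SyntheticWorldSpec()


@pytest.fixture(scope="session")
def world_climate(world_spec):
    return pc.make_synthetic_climate(world_spec)


@pytest.fixture(scope="session")
def world_inputs(world_climate):
    return prepare_engine_inputs(world_climate)


@pytest.fixture(scope="session")
def world_ei(world_inputs):
    return pc.run_grid(world_inputs, pc.ClimexParameters())


def one_cell_climate(tavg_months, rain_months, rh=70.0, lat=20.0, lon=10.0, half=2.0):
    """Single-cell monthly grid from 12 mean temperatures and rain totals."""
    t = np.asarray(tavg_months, float).reshape(12, 1, 1)
    r = np.asarray(rain_months, float).reshape(12, 1, 1)
    rh_arr = np.full((12, 1, 1), float(rh))
    return pc.MonthlyClimateGrid(
        lat_axis=np.array([lat]),
        lon_axis=np.array([lon]),
        tmin=t - half,
        tmax=t + half,
        rain=r,
        rh09=rh_arr,
        rh15=rh_arr,
    )


@pytest.fixture
def favourable_cell():
    """Mild (16-18 degC) winter-wet cell well inside the host's climatic optimum."""
    tavg = 17 + np.cos(2 * np.pi * (np.arange(12) - 0.5) / 12)
    rain = [110, 110, 100, 80, 40, 20, 15, 20, 40, 80, 100, 110]
    return one_cell_climate(tavg, rain)


@pytest.fixture
def polar_cell():
    return one_cell_climate(np.full(12, -20.0), np.full(12, 30.0), lat=80.0)


@pytest.fixture
def desert_cell():
    return one_cell_climate(np.full(12, 30.0), np.zeros(12), lat=25.0)
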