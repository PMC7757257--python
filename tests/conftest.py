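import numpy as np
import pytest

from gppclim import (
    ClimateScenario,
    GPPScenario,
    Grid,
    GriddedSeries,
    gen_climate,
    gen_gpp_ensemble,
)

DEFAULT_SEED = 1234


@pytest.fixture(scope="session")
def grid10():
    """The default 18 x 36 (10-degree) test grid."""
    return Grid.global_grid(10.0)


@pytest.fixture(scope="session")
def small_grid():
    return Grid.global_grid(30.0)  # 6 x 12


@pytest.fixture(scope="session")
def default_climate(grid10):
    return gen_climate(ClimateScenario(grid=grid10, seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_ensemble(grid10, default_climate):
    scen = GPPScenario.default(grid10, seed=DEFAULT_SEED)
    return gen_gpp_ensemble(default_climate, scen)


def make_series(values, grid, units="gC/m2/month", start_year=2000, name="field"):
    """Wrap a (T, nlat, nlon) array as a GriddedSeries with a monthly axis."""
    values = np.asarray(values, float)
    n = values.shape[0]
    code = np.arange(n)
    years = start_year + code // 12
    months = code % 12 + 1
    return GriddedSeries(values, years, months, grid, units, name=name)
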