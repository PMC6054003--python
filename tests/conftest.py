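import numpy as np
import pytest

from beanclim.raster import GridRaster
from beanclim.synthetic import SyntheticConfig, make_baseline_climate


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(grid_shape=(16, 16), seed=7, n_gcms=4)


@pytest.fixture(scope="session")
def small_region(small_cfg):
    """(MonthlyClimate, DEM) for a 16x16 synthetic region."""
    return make_baseline_climate(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_geom():
    """A 5x5 raster geometry with ~1 km cells near the equator."""
    return GridRaster(np.zeros((5, 5)), origin=(-86.0, 1.0),
                      cell_size=0.009)
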