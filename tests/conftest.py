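import numpy as np
import pytest

from hepsim.bioclim import DEFAULT_PREDICTORS, Standardizer, compute_bioclim
from hepsim.landscape_io import GridSpec
from hepsim import synthlab


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return GridSpec(nx=10, ny=8, cell_size=20.0, lon_origin=-6.0, lat_origin=38.0)


@pytest.fixture(scope="session")
def synth_spec():
    return synthlab.SynthSpec(nx=24, ny=24, seed=5)


@pytest.fixture(scope="session")
def landscape(synth_spec):
    return synthlab.generate_landscape(synth_spec)


@pytest.fixture(scope="session")
def warm_stack(synth_spec, landscape):
    clim = synthlab.generate_climate(synth_spec, landscape, "warm")
    return compute_bioclim(clim)


@pytest.fixture(scope="session")
def cold_stack(synth_spec, landscape):
    clim = synthlab.generate_climate(synth_spec, landscape, "cold")
    return compute_bioclim(clim)


@pytest.fixture(scope="session")
def pooled_standardizer(warm_stack, cold_stack):
    return Standardizer.fit_pooled([warm_stack, cold_stack],
                                   list(DEFAULT_PREDICTORS))


def uniform_land_grid(nx=10, ny=10, cell_size=20.0):
    """An all-land grid plus mask, for mobility/demography micro-worlds."""
    grid = GridSpec(nx=nx, ny=ny, cell_size=cell_size)
    return grid, np.ones(grid.shape, bool)
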