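import numpy as np
import pytest

from octostdp import (
    CellParams,
    ClickStimulus,
    MetricParams,
    PlasticityParams,
    assign_synapses,
    build_population,
    generate_raster,
)


@pytest.fixture(scope="session")
def population():
    """The standard 400-fiber, 6-20 kHz tonotopic axis."""
    return build_population()


@pytest.fixture(scope="session")
def small_population():
    """A 40-fiber axis for cheap end-to-end runs."""
    return build_population(n_fibers=40)


@pytest.fixture(scope="session")
def stimulus():
    return ClickStimulus()


@pytest.fixture(scope="session")
def cell_params():
    return CellParams()


@pytest.fixture(scope="session")
def metric_params():
    return MetricParams()


@pytest.fixture
def small_raster(small_population, stimulus):
    return generate_raster(small_population, stimulus, seed=42)


@pytest.fixture
def small_synapses(small_population):
    return assign_synapses(n_fibers=small_population.n_fibers, seed=3)
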