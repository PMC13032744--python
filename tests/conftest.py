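import numpy as np
import pytest

from spinefate import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def small_population():
    """A small but fully structured population shared across tests."""
    cfg = synthetic.SimulationConfig(
        n_animals=4, slices_per_animal=4, spines_per_dendrite=8, seed=7
    )
    spines, truth = synthetic.simulate_spine_population(cfg)
    return cfg, spines, truth
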