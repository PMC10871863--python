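import numpy as np
import pytest

from seqdecide import PopulationSpec, TaskDesign, simulate_dataset


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


@pytest.fixture(scope="session")
def small_dataset(design):
    """Mixed-selectivity population, 384 trials; shared across read-only tests."""
    spec = PopulationSpec(n_neurons=30, seed=2)
    return simulate_dataset(spec, design, n_per_slot=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
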