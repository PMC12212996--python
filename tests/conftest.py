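import numpy as np
import pytest

from abmda.infection import InfectionParams, init_infection
from abmda.wsg import WSGParams, init_wsg


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_wsg_params():
    return WSGParams(world_size=16, init_wolves=8, init_sheep=24, init_grass_density=0.5)


@pytest.fixture
def small_wsg_state(small_wsg_params):
    return init_wsg(small_wsg_params, seed=1)


@pytest.fixture
def small_infection_params():
    return InfectionParams(lattice_side=16, initial_infected_focus_radius=2)


@pytest.fixture
def small_infection_state(small_infection_params):
    return init_infection(small_infection_params, seed=2)
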