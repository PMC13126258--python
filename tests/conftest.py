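import numpy as np
import pytest

from rccsim import SimulationConfig, VirtualImage
from rccsim.genome import default_panel
from rccsim.host import HostProfile, initialize_host_state


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down simulation for fast tests: small arena, short horizon."""
    return SimulationConfig(width=60.0, height=60.0, max_steps=120,
                            lethal_burden=150, initial_vessels=2)


def make_image(sex="female", counts=None, **overrides) -> VirtualImage:
    state = initialize_host_state(HostProfile(sex=sex))
    fields = dict(
        counts=counts if counts is not None else state.counts,
        bmi=25.0,
        sex=sex,
        hormones=state.hormones,
        initial_mutation_load=state.initial_mutation_load,
        initial_cd8_exhaustion=state.initial_cd8_exhaustion,
        initial_cd8_activated_fraction=state.initial_cd8_activated_fraction,
    )
    fields.update(overrides)
    return VirtualImage(**fields)


@pytest.fixture()
def default_image():
    return make_image()


@pytest.fixture()
def tumor_only_image():
    """A virtual patient with no immune compartment at all."""
    return make_image(counts={"tumor": 40}, initial_mutation_load=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
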