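import numpy as np
import pytest

from opca import SynthSpec, degenerate_fixtures, random_chargeset, solve_water3, gas_phase_water_moments


@pytest.fixture(scope="session")
def fixtures():
    """Named degenerate charge distributions (built once: includes seed searches)."""
    return degenerate_fixtures()


@pytest.fixture(scope="session")
def water_solution():
    return solve_water3(gas_phase_water_moments())


@pytest.fixture
def rng():
    return np.random.default_rng(20130704)


def make_neutral(seed, **kw):
    return random_chargeset(SynthSpec(net_charge=0, seed=seed, **kw))


def make_charged(seed, net=1, **kw):
    return random_chargeset(SynthSpec(net_charge=net, seed=seed, **kw))
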