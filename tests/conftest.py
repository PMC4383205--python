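import numpy as np
import pytest

from rdcens.synthetic_data import (
    GeneratorSpec,
    make_rdc_tables,
    make_toy_protein,
    make_two_state_ensemble,
)


@pytest.fixture(scope="session")
def system():
    """One deterministic toy two-domain system shared across tests."""
    return make_toy_protein(GeneratorSpec(seed=11))


@pytest.fixture(scope="session")
def two_state(system):
    """A 60-frame two-state ensemble with its ground truth."""
    return make_two_state_ensemble(system, 60, seed=21)


@pytest.fixture(scope="session")
def rdc_table(system, two_state):
    ensemble, _ = two_state
    return make_rdc_tables(ensemble, system, seed=31)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
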