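import numpy as np
import pytest

from molrl.fixtures import fixture_graphs
from molrl.mol_graph import parse_smiles
from molrl.policy_net import init_params


@pytest.fixture(scope="session")
def corpus():
    return fixture_graphs()


@pytest.fixture(scope="session")
def aspirin():
    return parse_smiles("CC(=O)Oc1ccccc1C(=O)O")


@pytest.fixture(scope="session")
def params():
    """Randomly initialized (seeded) policy parameters."""
    return init_params(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
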