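"""Shared fixtures: small synthetic networks and default parameter sets."""

import numpy as np
import pytest

from ngnmm.connectome import generate_synthetic_connectome, row_normalize
from ngnmm.params import NetworkParameters, NodeParameters


@pytest.fixture(scope="session")
def conn4():
    """Row-normalised 4-region synthetic connectome (fixed seed)."""
    return row_normalize(generate_synthetic_connectome(4, seed=3))


@pytest.fixture(scope="session")
def conn6():
    """Row-normalised 6-region synthetic connectome (fixed seed)."""
    return row_normalize(generate_synthetic_connectome(6, seed=11))


@pytest.fixture(scope="session")
def node():
    return NodeParameters()


@pytest.fixture(scope="session")
def net_nonshunted():
    return NetworkParameters(shunting_network_input=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
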