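import numpy as np
import pytest

from mpqsar import GraphGenSpec, gen_graphs, parse_molecule


@pytest.fixture(scope="session")
def benzene():
    return parse_molecule("c1ccccc1")


@pytest.fixture(scope="session")
def nitrobenzene():
    return parse_molecule("O=[N+]([O-])c1ccccc1")


@pytest.fixture(scope="session")
def random_graphs():
    """100 random valence-respecting H-saturated graphs for oracle tests."""
    return gen_graphs(GraphGenSpec(n_heavy=(2, 8), seed=20240917), 100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
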