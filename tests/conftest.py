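import numpy as np
import pytest

from nsfkit import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def scenario1_quilt():
    """One scenario-I quilt replicate shared across read-only tests."""
    return sim.simulate_scenario1("quilt", n_features=200, seed=1)


@pytest.fixture(scope="session")
def scenario2_split():
    """One scenario-II split-mode quilt replicate."""
    return sim.simulate_scenario2("quilt", "split", n_features=500, seed=1)
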