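import numpy as np
import pytest

from aesthlearn.learner import run_simulation
from aesthlearn.params import standard_parameters


@pytest.fixture()
def standard():
    """(Individual, LearningConfig) at the standard parameter set."""
    return standard_parameters()


@pytest.fixture(scope="session")
def standard_trajectory():
    """One full 30k-step standard run, shared across tests."""
    individual, config = standard_parameters()
    return run_simulation(individual, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
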