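import numpy as np
import pytest

from cpmpaths.landscapes import DagOfRestrictions, fitness_graph_from_dag


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig1_dag():
    """Four genes; the fourth requires both the second AND the third."""
    return DagOfRestrictions(4, (0, 0, 0, 0b0110))


@pytest.fixture
def fig1_graph(fig1_dag):
    return fitness_graph_from_dag(fig1_dag)
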