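import numpy as np
import pytest

from markovcea import datasets


@pytest.fixture(scope="session")
def states():
    return datasets.STATES


@pytest.fixture(scope="session")
def matrix():
    return datasets.transition_matrix()


@pytest.fixture(scope="session")
def rewards():
    return datasets.rewards()


@pytest.fixture(scope="session")
def discount():
    return datasets.discount()


@pytest.fixture(scope="session")
def intervention():
    return datasets.intervention()


@pytest.fixture(scope="session")
def all_severe():
    return np.array([0.0, 0.0, 1.0, 0.0, 0.0])
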