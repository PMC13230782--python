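import numpy as np
import pytest
from hypothesis import settings

from cosref import ModularNetwork

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_net() -> ModularNetwork:
    """Two triangles joined by one bridge: A = {0,1,2}, B = {3,4,5}, bridge 2-3.

    7 edges, 1 inter edge -> mu = 1/7; every intra degree is 2.
    """
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    return ModularNetwork(community_labels=[0, 0, 0, 1, 1, 1], edges=np.array(edges))


@pytest.fixture
def rng():
    return np.random.Generator(np.random.MT19937(1234))
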