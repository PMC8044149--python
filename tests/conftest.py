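import numpy as np
import pytest

from neurocast.graph import Graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng: np.random.Generator, n: int) -> Graph:
    """Random connected symmetric weighted graph on n nodes."""
    a = np.abs(rng.normal(size=(n, n))) + 0.05
    a = a + a.T
    np.fill_diagonal(a, 0.0)
    return Graph(adjacency=a)


@pytest.fixture
def graph5(rng):
    return random_graph(rng, 5)
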