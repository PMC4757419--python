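import networkx as nx
import numpy as np
import pytest

import netillusion as ni


@pytest.fixture
def star5():
    """K_{1,4}: hub 0 plus four leaves."""
    return nx.star_graph(4)


@pytest.fixture
def triangle():
    return nx.cycle_graph(3)


@pytest.fixture
def path3():
    """Path a-b-c with node 1 in the middle."""
    return nx.path_graph(3)


@pytest.fixture(scope="session")
def medium_powerlaw():
    """A 3,000-node heavy-tailed configuration-model graph (session-cached)."""
    spec = ni.PowerLawSpec(alpha=2.5, n_nodes=3000, k_min=1)
    return ni.powerlaw_graph(spec, rng_seed=42)


@pytest.fixture(scope="session")
def medium_er():
    """A 3,000-node ER graph with mean degree ~5 (session-cached)."""
    return ni.erdos_renyi_mean_degree(3000, 5.0, rng_seed=42)


def random_simple_graph(n_nodes: int, n_edges: int, seed: int) -> nx.Graph:
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
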