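import numpy as np
import pytest

from mumseir import ModelParams, TwoLayerNetwork


@pytest.fixture
def baseline():
    """Baseline parameter set used across the experiment suite."""
    return ModelParams()


def adjacency_from_edges(n, edges):
    adj = np.zeros((n, n))
    for u, v in edges:
        adj[u, v] = adj[v, u] = 1.0
    return adj


@pytest.fixture
def path3():
    """Path graph 0-1-2, same topology on both layers."""
    adj = adjacency_from_edges(3, [(0, 1), (1, 2)])
    return TwoLayerNetwork(upper=adj.copy(), lower=adj.copy())


@pytest.fixture
def k5():
    """Complete graph on five nodes, both layers."""
    adj = 1.0 - np.eye(5)
    return TwoLayerNetwork(upper=adj.copy(), lower=adj.copy())


def star_network(n):
    """Star with hub 0 and n-1 leaves, both layers."""
    adj = adjacency_from_edges(n, [(0, i) for i in range(1, n)])
    return TwoLayerNetwork(upper=adj.copy(), lower=adj.copy())
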