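import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dynconn.windows import BinaryDynamicNetwork, WeightedDynamicNetwork


def symmetric_layers(rng, T, N):
    """Random symmetric weighted layers with zero diagonal, entries in [-1, 1]."""
    raw = rng.uniform(-1, 1, size=(T, N, N))
    layers = (raw + raw.transpose(0, 2, 1)) / 2
    for t in range(T):
        np.fill_diagonal(layers[t], 0.0)
    return layers


def random_weighted_net(rng, T, N) -> WeightedDynamicNetwork:
    return WeightedDynamicNetwork(layers=symmetric_layers(rng, T, N))


def random_binary_net(rng, T, N, p=0.4, sparsity=0.4) -> BinaryDynamicNetwork:
    layers = np.zeros((T, N, N), dtype=bool)
    iu = np.triu_indices(N, 1)
    for t in range(T):
        mask = rng.random(iu[0].size) < p
        layers[t][iu] = mask
        layers[t] |= layers[t].T
    return BinaryDynamicNetwork(layers=layers, sparsity=sparsity)


def net_from_edges(edge_lists, N, sparsity=0.4) -> BinaryDynamicNetwork:
    """Binary dynamic network from per-layer 0-based undirected edge lists."""
    T = len(edge_lists)
    layers = np.zeros((T, N, N), dtype=bool)
    for t, edges in enumerate(edge_lists):
        for i, j in edges:
            layers[t, i, j] = layers[t, j, i] = True
    return BinaryDynamicNetwork(layers=layers, sparsity=sparsity)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
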