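import itertools

import numpy as np
import pytest

from pnetalign import UncertainNetwork


@pytest.fixture
def star_net() -> UncertainNetwork:
    """Node 'a' with two incident edges of probabilities 0.4 and 0.9."""
    return UncertainNetwork(edges=[("a", "b", 0.4), ("a", "c", 0.9)])


@pytest.fixture
def triangle_det() -> UncertainNetwork:
    return UncertainNetwork(edges=[("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])


def random_uncertain_network(
    rng: np.random.Generator,
    n_nodes: int,
    max_edges: int,
    prefix: str = "n",
    p_low: float = 0.05,
) -> UncertainNetwork:
    """Small random uncertain network for oracle comparisons."""
    labels = [f"{prefix}{i}" for i in range(n_nodes)]
    net = UncertainNetwork(nodes=labels)
    pairs = list(itertools.combinations(labels, 2))
    rng.shuffle(pairs)
    k = int(rng.integers(1, max_edges + 1))
    for a, b in pairs[:k]:
        net.add_edge(a, b, float(rng.uniform(p_low, 1.0)))
    return net
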