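import numpy as np
import pytest

from rhizonet import simulate as sim
from rhizonet.datamodel import Evidence, InteractionNetwork


def make_net(edges, nodes=()):
    """Small literal network from an iterable of (u, v) pairs."""
    net = InteractionNetwork()
    for n in nodes:
        net.ensure_protein(n)
    for u, v in edges:
        net.add_edge(u, v, Evidence(kind="experimental"))
    return net


def random_simple_net(rng, n_max=15, p=None):
    """Random Erdos-Renyi network on string ids for oracle comparisons."""
    n = int(rng.integers(4, n_max + 1))
    p = p if p is not None else float(rng.uniform(0.15, 0.5))
    net = InteractionNetwork()
    ids = [f"n{i:02d}" for i in range(n)]
    for i in ids:
        net.ensure_protein(i)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(ids[i], ids[j], Evidence(kind="experimental"))
    return net


@pytest.fixture
def triangle():
    return make_net([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def snf_scenario():
    return sim.make_snf_scenario(sim.SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
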