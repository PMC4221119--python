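import networkx as nx
import numpy as np
import pytest

import exomewalker as ew


@pytest.fixture
def path_net():
    """Path graph A - B - C."""
    return ew.network_from_edges([("A", "B", 0.9), ("B", "C", 0.8)])


@pytest.fixture
def pair_net():
    """Single edge A - B."""
    return ew.network_from_edges([("A", "B", 0.9)])


@pytest.fixture
def triangle_net():
    return ew.network_from_edges(
        [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.85)]
    )


def random_connected_network(rng, n_max=200):
    """Random connected graph as a PPANetwork, node names sortable strings."""
    n = int(rng.integers(5, n_max + 1))
    p = max(0.05, 2.5 * np.log(n) / n)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    # connect components along a random spanning chain
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    g.remove_edges_from(nx.selfloop_edges(g))
    edges = [(f"N{u:04d}", f"N{v:04d}", float(rng.uniform(0.7, 1.0))) for u, v in g.edges]
    return ew.network_from_edges(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_731)


@pytest.fixture(scope="session")
def trained_model():
    """One surrogate combiner model shared across the suite."""
    return ew.default_model()


@pytest.fixture(scope="session")
def fixture_study():
    """The standard synthetic study: planted-module network, 20 families,
    5 background exomes and spike-in records (all seeded)."""
    cfg = ew.FixtureConfig(rng_seed=11)
    net, families = ew.generate_network(cfg)
    backgrounds = [
        ew.generate_exome(cfg, genes=list(net.genes), seed=1100 + i) for i in range(5)
    ]
    records = ew.benchmark.make_spike_records(families, seed=42)
    return cfg, net, families, backgrounds, records
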