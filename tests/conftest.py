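import networkx as nx
import numpy as np
import pytest

import scnet


@pytest.fixture
def small_ref():
    """10-gene, 15-edge weighted reference graph."""
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(10)]
    g = nx.Graph()
    pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
    for i, j in [pairs[k] for k in rng.choice(len(pairs), size=15, replace=False)]:
        g.add_edge(genes[i], genes[j], weight=float(rng.uniform(1, 3)))
    return g


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edge("A", "B", weight=1.0)
    g.add_edge("B", "C", weight=2.0)
    g.add_edge("A", "C", weight=3.0)
    return g


def random_weighted_graph(n_nodes, p, seed, low=1.0, high=3.0):
    """ER graph with Uniform(low, high) edge weights and string labels."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"g{i:03d}" for i in g.nodes})
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(low, high))
    return g


@pytest.fixture
def sim_cfg():
    return scnet.SimulationConfig(seed=0)
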