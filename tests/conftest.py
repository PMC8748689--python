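import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netmias as nm


@pytest.fixture
def path_graph():
    """A -- B -- C."""
    return nm.build_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star_graph():
    """Center C with leaves L1..L3."""
    return nm.build_network([("C", "L1"), ("C", "L2"), ("C", "L3")])


@pytest.fixture
def random_networks():
    """Seeded list of (GeneNetwork, nx.Graph) random graphs for oracles."""
    out = []
    rng = np.random.default_rng(42)
    for k in range(20):
        n = int(rng.integers(5, 60))
        g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
        edges = [(f"N{a:03d}", f"N{b:03d}") for a, b in g.edges()]
        if not edges:
            continue
        out.append(nm.build_network(edges))
    return out


def brute_force_betweenness(net):
    """Exhaustive BFS shortest-path enumeration oracle."""
    g = net.to_networkx()
    bc = {v: 0.0 for v in net.nodes}
    nodes = list(net.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def toy_ranked(scores: dict) -> nm.RankedList:
    return nm.rank_and_percentile(pd.Series(scores, dtype=float))
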