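"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the code paths of the package:
betweenness by explicit shortest-path enumeration, subgraph centrality by a
truncated matrix-power series, information centrality by a direct
double-loop over the inverted matrix, and the hypergeometric tail by
counting subsets.  They exist to cross-check the production implementations
on small inputs.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from censignet.network import InteractionNetwork


# Support histogram of the published collection of 94 human breast cancer
# signatures (number of genes found in exactly f signatures).  Used as a
# worked-example input for the overlap summary statistics.
PUBLISHED_OVERLAP_HISTOGRAM = {
    1: 4143, 2: 1608, 3: 687, 4: 323, 5: 148, 6: 56, 7: 40, 8: 23,
    9: 15, 10: 13, 11: 4, 12: 3, 14: 1, 15: 1, 16: 1, 17: 1,
}


def make_net(edges, nodes=()) -> InteractionNetwork:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return InteractionNetwork(graph=g, name="test")


def random_net(seed: int, n_max: int = 8) -> InteractionNetwork:
    """Random simple graph with 2..n_max nodes and string labels."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    return InteractionNetwork(graph=g, name=f"rand{seed}")


# ---------------------------------------------------------------- oracles --

def oracle_betweenness(net: InteractionNetwork) -> dict[str, float]:
    """Sum over unordered pairs of the fraction of shortest paths through i,
    by explicit enumeration of every shortest path."""
    g = net.graph
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def oracle_closeness(net: InteractionNetwork) -> dict[str, float]:
    cc = {}
    for v in net.graph.nodes:
        dists = nx.single_source_shortest_path_length(net.graph, v)
        total = sum(d for u, d in dists.items() if u != v)
        cc[v] = 1.0 / total if total > 0 else 0.0
    return cc


def oracle_subgraph(net: InteractionNetwork, lmax: int = 60) -> dict[str, float]:
    """Closed-walk series sum_{l<=lmax} (A^l)_ii / l! via repeated powers."""
    order = sorted(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=order)
    acc = np.eye(len(order))
    power = np.eye(len(order))
    fact = 1.0
    for l in range(1, lmax + 1):
        power = power @ a
        fact *= l
        acc = acc + power / fact
    return {v: float(acc[i, i]) for i, v in enumerate(order)}


def oracle_eigenvector(net: InteractionNetwork, iters: int = 5000) -> dict[str, float]:
    """Power iteration on A + I (shift keeps the dominant pair unique on
    connected non-bipartite-safe inputs); unit-norm absolute vector."""
    order = sorted(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=order) + np.eye(len(order))
    x = np.full(len(order), 1.0 / math.sqrt(len(order)))
    for _ in range(iters):
        x = a @ x
        x = x / np.linalg.norm(x)
    x = np.abs(x)
    x = x / np.linalg.norm(x)
    return {v: float(s) for v, s in zip(order, x)}


def oracle_information(net: InteractionNetwork, cross: float = 2.0) -> dict[str, float]:
    """Direct inversion of D - A + J per component with an explicit pair loop."""
    out = {}
    for comp in nx.connected_components(net.graph):
        members = sorted(comp)
        m = len(members)
        if m == 1:
            out[members[0]] = 0.0
            continue
        a = nx.to_numpy_array(net.graph, nodelist=members)
        b = np.diag(a.sum(axis=1)) - a + np.ones((m, m))
        r = np.linalg.inv(b)
        for i, v in enumerate(members):
            total = 0.0
            for j in range(m):
                if j == i:
                    continue
                total += r[i, i] + r[j, j] - cross * r[i, j]
            out[v] = m / total
    return out


def oracle_hypergeom_tail(G: int, n: int, C: int, k: int) -> float:
    """Pr(overlap >= k) by enumerating every C-subset of a G-element universe
    whose first n elements are 'annotated'."""
    annotated = set(range(n))
    hits = 0
    total = 0
    for subset in itertools.combinations(range(G), C):
        total += 1
        if len(annotated.intersection(subset)) >= k:
            hits += 1
    return hits / total


@pytest.fixture
def p3() -> InteractionNetwork:
    return make_net([("A", "B"), ("B", "C")])


@pytest.fixture
def star4() -> InteractionNetwork:
    return make_net([("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3")])


@pytest.fixture
def triangle() -> InteractionNetwork:
    return make_net([("A", "B"), ("B", "C"), ("A", "C")])
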