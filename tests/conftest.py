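"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they check: distances come
from scipy's Floyd–Warshall on a dense adjacency matrix (not networkx BFS),
clustering from explicit triangle enumeration, components from an iterative
depth-first search, hub moments from the statistics module, and the
hypergeometric tail from exhaustive enumeration of all draws.
"""

from __future__ import annotations

import itertools
import math
import statistics
from math import comb

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from mirnome.network_build import GeneNetwork


def net_from_edges(edges, isolated=(), label="test") -> GeneNetwork:
    g = nx.Graph()
    g.add_nodes_from(str(n) for n in isolated)
    g.add_edges_from((str(a), str(b)) for a, b in edges)
    return GeneNetwork(graph=g, label=label)


def random_network(rng: np.random.Generator, n_max: int = 30) -> GeneNetwork:
    """A small random graph, sometimes with extra isolated nodes."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.0, 0.35))
    g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
    for i in range(int(rng.integers(0, 4))):
        g.add_node(f"iso{i}")
    return GeneNetwork(graph=g)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_path_stats(network: GeneNetwork) -> tuple[int, float, float, int]:
    """All-pairs distances via Floyd–Warshall on the dense adjacency matrix."""
    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n))
    for a, b in network.graph.edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1.0
    dist = floyd_warshall(adj, unweighted=True)
    finite = dist[(dist > 0) & np.isfinite(dist)]
    n_pairs = int(finite.size)
    pct = 100.0 * n_pairs / (n * (n - 1)) if n > 1 else 0.0
    cpl = float(finite.mean()) if n_pairs else math.nan
    diameter = int(finite.max()) if n_pairs else 0
    return n_pairs, pct, cpl, diameter


def oracle_clustering(network: GeneNetwork) -> dict[str, float]:
    """Per-node clustering by explicit enumeration of neighbour pairs."""
    out = {}
    g = network.graph
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            out[node] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        out[node] = 2.0 * links / (k * (k - 1))
    return out


def oracle_components(network: GeneNetwork) -> list[frozenset[str]]:
    """Connected components by iterative depth-first search."""
    seen: set[str] = set()
    comps = []
    for start in network.graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(w for w in network.graph.neighbors(v) if w not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def oracle_hubs(network: GeneNetwork) -> tuple[float, float, set[str]]:
    """Brute-force hub filter from independently computed moments."""
    degrees = {v: network.graph.degree(v) for v in network.graph.nodes}
    mu = statistics.mean(degrees.values())
    sigma = statistics.pstdev(degrees.values())
    return mu, sigma, {v for v, d in degrees.items() if d > mu + sigma}


def oracle_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by exhaustive enumeration over all C(N, n) draws (N <= 12)."""
    population = list(range(N))
    successes = set(range(K))
    hits = sum(
        1
        for draw in itertools.combinations(population, n)
        if len(successes.intersection(draw)) >= k
    )
    return hits / comb(N, n)


@pytest.fixture
def triangle() -> GeneNetwork:
    return net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star5() -> GeneNetwork:
    return net_from_edges([("hub", f"leaf{i}") for i in range(5)])
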