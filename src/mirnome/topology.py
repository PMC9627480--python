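"""Topology statistics, scale-free degree-distribution fit, hierarchy test.

Conventions (fixed across the package):

* Shortest paths are counted over *ordered* node pairs (n, m), n != m, with
  a finite distance; on a connected graph that is N(N-1) pairs. The
  characteristic path length is the mean distance over those pairs and the
  diameter is the maximum finite distance, which keeps it well-defined on
  disconnected networks.
* The per-node clustering coefficient is the Watts–Strogatz
  C_i = 2 n_i / (k_i (k_i - 1)) for degree k_i >= 2 (n_i = links among the
  neighbours); the network average is taken over eligible nodes (k >= 2)
  by default, with an ``all_nodes`` mode counting k < 2 nodes as C = 0.
* The power law P(k) ~ k^gamma is fitted by ordinary least squares of
  log10(count) on log10(k) over positive-count degrees k >= 1 (no binning,
  no k_min cutoff). R^2 is the determination coefficient of that log-log
  regression; R is the Pearson correlation between observed counts and the
  fitted a*k^gamma on the original scale, so the two statistics answer
  different questions and need not satisfy R^2 = R*R.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_build import GeneNetwork, connected_components


class FitError(ValueError):
    """Raised when a regression has too few points to be meaningful."""


@dataclass
class TopologyReport:
    """Machine-readable topology summary of one network."""

    label: str
    n_nodes: int
    n_edges: int
    n_components: int
    avg_clustering: float
    diameter: int
    n_shortest_paths: int
    shortest_paths_pct: float
    char_path_length: float
    avg_neighbors: float


@dataclass
class DegreeDistribution:
    """Histogram of node degrees; degree-0 nodes kept apart from the fit."""

    counts: dict[int, int]  # degree k >= 1 -> number of nodes
    n_zero: int
    n_nodes: int

    def probability(self, k: int) -> float:
        if k == 0:
            return self.n_zero / self.n_nodes
        return self.counts.get(k, 0) / self.n_nodes


@dataclass
class PowerLawFit:
    gamma: float        # slope of the log10-log10 regression
    intercept: float    # log10 of the prefactor a
    r: float            # Pearson r, observed vs fitted counts, original scale
    r_squared: float    # determination coefficient of the log-log fit
    n_points: int


@dataclass
class HierarchyAssessment:
    """Log-log regression of mean clustering C(k) on degree k.

    A hierarchical (deterministic-modular) network shows C(k) ~ k^-1 with a
    tight fit; a plain preferential-attachment network does not. ``verdict``
    is None when fewer than two usable (k, C(k) > 0) points exist.
    """

    slope: float
    r_squared: float
    verdict: bool | None
    n_points: int


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def degree_sequence(network: GeneNetwork) -> dict[str, int]:
    """Per-node degree (distinct neighbours; the graph carries no self-loops)."""
    return dict(network.graph.degree())


def avg_neighbors(network: GeneNetwork) -> float:
    """Mean number of neighbours, 2E/N."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return 2.0 * network.n_edges / network.n_nodes


def clustering_coefficient(
    network: GeneNetwork, mode: str = "eligible_only"
) -> tuple[dict[str, float], float]:
    """Per-node clustering plus the network average.

    ``eligible_only`` (default) averages over nodes with degree >= 2;
    ``all_nodes`` averages over every node, counting k < 2 nodes as 0.
    """
    per_node = nx.clustering(network.graph)
    per_node = {n: float(c) for n, c in per_node.items()}
    if mode == "eligible_only":
        eligible = [c for n, c in per_node.items() if network.graph.degree(n) >= 2]
        average = float(np.mean(eligible)) if eligible else 0.0
    elif mode == "all_nodes":
        average = float(np.mean(list(per_node.values()))) if per_node else 0.0
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    return per_node, average


def shortest_path_stats(network: GeneNetwork) -> tuple[int, float, float, int]:
    """(n_shortest_paths, pct, characteristic path length, diameter).

    BFS from every node; ordered connected pairs are counted, their mean
    distance is the characteristic path length, and the diameter is the
    longest finite shortest path. An edgeless network reports
    (0, 0.0, nan, 0).
    """
    n = network.n_nodes
    if n == 0:
        raise ValueError("empty network")
    n_pairs = 0
    total = 0
    diameter = 0
    for source in network.graph.nodes:
        lengths = nx.single_source_shortest_path_length(network.graph, source)
        for target, d in lengths.items():
            if d > 0:
                n_pairs += 1
                total += d
                if d > diameter:
                    diameter = d
    possible = n * (n - 1)
    pct = 100.0 * n_pairs / possible if possible else 0.0
    cpl = total / n_pairs if n_pairs else math.nan
    return n_pairs, pct, cpl, diameter


def degree_distribution(network: GeneNetwork) -> DegreeDistribution:
    degrees = Counter(d for _, d in network.graph.degree())
    n_zero = degrees.pop(0, 0)
    return DegreeDistribution(
        counts=dict(sorted(degrees.items())), n_zero=n_zero, n_nodes=network.n_nodes
    )


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------


def _loglog_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of log10 y on log10 x; returns (slope, intercept, r_squared)."""
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    if ss_tot == 0.0:
        # degenerate: constant response; a flat fit explains it exactly
        r_squared = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r_squared = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r_squared


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Fit count(k) ~ a * k^gamma on logarithmized data (degrees k >= 1)."""
    ks = np.array([k for k, c in dist.counts.items() if c > 0], dtype=float)
    cs = np.array([c for c in dist.counts.values() if c > 0], dtype=float)
    if len(ks) < 2:
        raise FitError("power-law fit needs at least 2 distinct degrees")
    gamma, intercept, r_squared = _loglog_ols(ks, cs)
    fitted = 10.0 ** intercept * ks ** gamma
    if np.std(fitted) == 0.0 or np.std(cs) == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(cs, fitted)[0, 1])
    return PowerLawFit(
        gamma=gamma, intercept=intercept, r=r, r_squared=r_squared, n_points=len(ks)
    )


def assess_hierarchy(network: GeneNetwork, cutoff: float = 0.5) -> HierarchyAssessment:
    """Regress mean clustering C(k) on degree k (log-log, k >= 2, C(k) > 0).

    ``verdict`` is True (hierarchical) when the determination coefficient
    reaches ``cutoff``; None when fewer than two usable points exist.
    """
    per_node, _ = clustering_coefficient(network)
    by_k: dict[int, list[float]] = {}
    for node, c in per_node.items():
        k = network.graph.degree(node)
        if k >= 2:
            by_k.setdefault(k, []).append(c)
    pts = [(k, float(np.mean(cs))) for k, cs in sorted(by_k.items())]
    pts = [(k, c) for k, c in pts if c > 0]
    if len(pts) < 2:
        return HierarchyAssessment(
            slope=math.nan, r_squared=math.nan, verdict=None, n_points=len(pts)
        )
    ks = np.array([k for k, _ in pts], dtype=float)
    cs = np.array([c for _, c in pts], dtype=float)
    slope, _, r_squared = _loglog_ols(ks, cs)
    return HierarchyAssessment(
        slope=slope, r_squared=r_squared, verdict=r_squared >= cutoff, n_points=len(pts)
    )


def topology_report(network: GeneNetwork, label: str | None = None) -> TopologyReport:
    """Aggregate all topology statistics into one report."""
    n_pairs, pct, cpl, diameter = shortest_path_stats(network)
    _, avg_c = clustering_coefficient(network)
    return TopologyReport(
        label=label if label is not None else network.label,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        n_components=len(connected_components(network)),
        avg_clustering=avg_c,
        diameter=diameter,
        n_shortest_paths=n_pairs,
        shortest_paths_pct=pct,
        char_path_length=cpl,
        avg_neighbors=avg_neighbors(network),
    )
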