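"""Global topology statistics of a predicted interaction network.

Biological interaction networks are expected to be scale-free (degree
distribution P(k) ~ k^-gamma, a few highly connected hubs among many
low-degree proteins) and small-world (short average path length L combined
with clustering far above a size-matched random graph).  This module
computes the degree census, a log-log least-squares power-law fit, the
average shortest path length over connected pairs, the mean local
clustering coefficient, and a seeded uniform G(n, m) random reference for
the small-world comparison.

Conventions: self-loops contribute 1 to degree, are ignored for paths and
excluded from neighbor sets when clustering; L averages over connected
pairs of distinct nodes only (unreachable pairs are excluded from numerator
and denominator); nodes of degree < 2 have local clustering 0 and are
included in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

__all__ = [
    "NetworkStats",
    "SmallWorldReport",
    "degree_distribution",
    "fit_power_law",
    "average_path_length",
    "clustering_coefficient",
    "network_stats",
    "random_reference",
    "small_world_report",
]


@dataclass
class NetworkStats:
    """Summary of the global topology of one network."""

    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    gamma: float | None
    avg_path_length: float | None
    clustering_coefficient: float
    diameter: int | None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "gamma": self.gamma,
            "avg_path_length": self.avg_path_length,
            "clustering_coefficient": self.clustering_coefficient,
            "diameter": self.diameter,
        }


def _simple(network: nx.Graph) -> nx.Graph:
    """Copy of the network without self-loops."""
    g = network.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def degree_distribution(network: nx.Graph) -> dict[int, int]:
    """Exact degree census (degree k -> number of nodes); self-loops count 1."""
    hist: dict[int, int] = {}
    for node in network.nodes:
        k = network.degree(node)
        if network.has_edge(node, node):
            k -= 1
        hist[k] = hist.get(k, 0) + 1
    return hist


def fit_power_law(histogram: Mapping[int, int]) -> float:
    """Exponent gamma of P(k) ~ k^-gamma by least squares on log10-log10 axes.

    Fits log10 P(k) against log10 k over degrees k >= 1 with nonzero counts
    and returns the negated slope.  Requires at least 3 support points.
    """
    ks = np.array(sorted(k for k, c in histogram.items() if k >= 1 and c > 0), dtype=float)
    if ks.size < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct degrees with nonzero counts, got {ks.size}"
        )
    total = sum(c for k, c in histogram.items() if k >= 1 and c > 0)
    pk = np.array([histogram[int(k)] / total for k in ks])
    slope, _ = np.polyfit(np.log10(ks), np.log10(pk), 1)
    return float(-slope)


def _path_length_sums(network: nx.Graph) -> tuple[float, int, int]:
    """(sum of distances, number of connected unordered pairs, max distance)."""
    g = _simple(network)
    total = 0.0
    count = 0
    longest = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target == source:
                continue
            total += dist
            count += 1
            longest = max(longest, dist)
    # each unordered pair visited twice
    return total / 2.0, count // 2, longest


def average_path_length(network: nx.Graph) -> float:
    """Mean shortest-path length over connected pairs of distinct nodes."""
    if network.number_of_nodes() < 2:
        raise ValueError("average path length needs >= 2 nodes")
    total, count, _ = _path_length_sums(network)
    if count == 0:
        raise ValueError("no connected pair of distinct nodes")
    return total / count


def clustering_coefficient(network: nx.Graph) -> float:
    """Mean local clustering C_i over all nodes (C_i = 0 for degree < 2)."""
    if network.number_of_nodes() < 1:
        raise ValueError("clustering needs >= 1 node")
    return float(nx.average_clustering(_simple(network), count_zeros=True))


def network_stats(network: nx.Graph) -> NetworkStats:
    """All global statistics of a network in one pass."""
    hist = degree_distribution(network)
    try:
        gamma = fit_power_law(hist)
    except ValueError:
        gamma = None
    try:
        total, count, longest = _path_length_sums(network)
        avg_l = total / count if count else None
        diameter = longest if count else None
    except ValueError:
        avg_l, diameter = None, None
    return NetworkStats(
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        degree_histogram=hist,
        gamma=gamma,
        avg_path_length=avg_l,
        clustering_coefficient=clustering_coefficient(network)
        if network.number_of_nodes()
        else 0.0,
        diameter=diameter,
    )


def random_reference(n_nodes: int, n_edges: int, seed: int) -> nx.Graph:
    """Uniform random simple graph with exactly n_nodes and n_edges (G(n, m))."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (max {max_edges})"
        )
    return nx.gnm_random_graph(n_nodes, n_edges, seed=seed)


@dataclass
class SmallWorldReport:
    """Network vs random-reference comparison for the small-world judgement."""

    avg_path_length: float
    clustering: float
    random_avg_path_length: float
    random_clustering: float
    n_reference: int
    path_length_ge_random: bool = field(init=False)
    clustering_ratio: float = field(init=False)
    clustering_exceeds_random: bool = field(init=False)
    ratio_threshold: float = 2.0

    def __post_init__(self) -> None:
        self.path_length_ge_random = self.avg_path_length >= self.random_avg_path_length
        self.clustering_ratio = (
            self.clustering / self.random_clustering
            if self.random_clustering > 0
            else float("inf")
        )
        self.clustering_exceeds_random = self.clustering_ratio > self.ratio_threshold

    def to_dict(self) -> dict:
        return {
            "avg_path_length": self.avg_path_length,
            "clustering": self.clustering,
            "random_avg_path_length": self.random_avg_path_length,
            "random_clustering": self.random_clustering,
            "n_reference": self.n_reference,
            "path_length_ge_random": self.path_length_ge_random,
            "clustering_ratio": self.clustering_ratio,
            "clustering_exceeds_random": self.clustering_exceeds_random,
            "ratio_threshold": self.ratio_threshold,
        }


def small_world_report(
    network: nx.Graph,
    seed: int,
    n_reference: int = 10,
    ratio_threshold: float = 2.0,
) -> SmallWorldReport:
    """Compare (L, C) of the network against seeded G(n, m) references.

    A small-world network keeps L close to (but not below) the random
    expectation while its clustering exceeds the random level by a large
    factor (default judgement threshold: 2x).
    """
    g = _simple(network)
    L = average_path_length(g)
    C = clustering_coefficient(g)
    n, m = g.number_of_nodes(), g.number_of_edges()
    l_rand, c_rand = [], []
    for i in range(n_reference):
        ref = random_reference(n, m, seed=seed + i)
        l_rand.append(average_path_length(ref))
        c_rand.append(clustering_coefficient(ref))
    return SmallWorldReport(
        avg_path_length=L,
        clustering=C,
        random_avg_path_length=float(np.mean(l_rand)),
        random_clustering=float(np.mean(c_rand)),
        n_reference=n_reference,
        ratio_threshold=ratio_threshold,
    )
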