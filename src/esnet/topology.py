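"""Graph metrics of thresholded networks.

Degree, normalized betweenness centrality, global efficiency, Louvain
modularity, degree assortativity over edge-end degree pairs, hub flags, and
regional summaries. Shortest-path machinery is delegated to networkx; the
assortativity coefficient is evaluated directly from its edge-pair
definition so that the regular-graph degenerate case (zero variance of
edge-end degrees) surfaces as an explicit missing value instead of a
division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import BinaryNetwork
from .session.types import REGIONS


def to_graph(net: BinaryNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.adjacency)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


@dataclass
class GraphMetrics:
    degree: np.ndarray
    bc: np.ndarray
    ge: float
    modularity_q: float
    partition: list[set[int]]
    assortativity: float | None
    hub_flags: np.ndarray


def node_degrees(net: BinaryNetwork) -> np.ndarray:
    return net.adjacency.sum(axis=1)


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """Betweenness normalized by (n-1)(n-2)/2; disconnected pairs contribute 0."""
    n = net.n_nodes
    if n < 3:
        raise ValueError("betweenness normalization undefined for n < 3")
    bc = nx.betweenness_centrality(to_graph(net), normalized=True)
    return np.array([bc[i] for i in range(n)])


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over pairs, 1/inf = 0 when disconnected."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency undefined for n < 2")
    return float(nx.global_efficiency(to_graph(net)))


def modularity_q(g: nx.Graph, partition: list[set[int]]) -> float:
    return float(nx.community.modularity(g, partition))


def louvain_modularity(net: BinaryNetwork, seed: int = 0,
                       n_restarts: int = 10) -> tuple[list[set[int]], float]:
    """Louvain partition, best Q over seeded restarts."""
    if net.n_edges == 0:
        raise ValueError("Louvain undefined on an edgeless graph")
    g = to_graph(net)
    best_part, best_q = None, -np.inf
    for k in range(n_restarts):
        part = nx.community.louvain_communities(g, seed=seed + k)
        q = modularity_q(g, part)
        if q > best_q:
            best_part, best_q = part, q
    return best_part, best_q


def assortativity(net: BinaryNetwork) -> float | None:
    """Degree correlation over edge-end pairs (j_i, k_i), i = 1..L.

    Returns None on regular graphs, where the denominator vanishes.
    """
    edges = net.edges()
    if len(edges) == 0:
        raise ValueError("assortativity undefined on an edgeless graph")
    deg = node_degrees(net)
    j = deg[edges[:, 0]].astype(float)
    k = deg[edges[:, 1]].astype(float)
    mean_prod = np.mean(j * k)
    mean_sum_half = np.mean(0.5 * (j + k))
    mean_sq_half = np.mean(0.5 * (j ** 2 + k ** 2))
    denom = mean_sq_half - mean_sum_half ** 2
    if np.isclose(denom, 0.0, atol=1e-12):
        return None
    return float((mean_prod - mean_sum_half ** 2) / denom)


def hub_flags(degree: np.ndarray, bc: np.ndarray,
              quantile: float = 0.8) -> np.ndarray:
    """Flag nodes in the top (1-quantile) of degree or betweenness.

    The cutoff is a convention; the underlying definition of a hub (high
    degree and/or high BC) has no canonical threshold.
    """
    dq = np.quantile(degree, quantile)
    bq = np.quantile(bc, quantile)
    return (degree >= dq) | (bc >= bq)


def compute_metrics(net: BinaryNetwork, seed: int = 0,
                    n_restarts: int = 10, hub_quantile: float = 0.8) -> GraphMetrics:
    deg = node_degrees(net)
    bc = betweenness_centrality(net)
    part, q = louvain_modularity(net, seed=seed, n_restarts=n_restarts)
    return GraphMetrics(
        degree=deg,
        bc=bc,
        ge=global_efficiency(net),
        modularity_q=q,
        partition=part,
        assortativity=assortativity(net),
        hub_flags=hub_flags(deg, bc, hub_quantile),
    )


def regional_topography(metric: np.ndarray, regions: list[str]) -> dict[str, float]:
    """Mean of a per-node metric within each region present in the montage."""
    metric = np.asarray(metric, dtype=float)
    out: dict[str, float] = {}
    regions_arr = np.array(regions)
    for region in REGIONS:
        mask = regions_arr == region
        if mask.any():
            out[region] = float(metric[mask].mean())
    if not out:
        raise ValueError("no populated regions")
    return out
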