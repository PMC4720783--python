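"""Oscillator-network construction: topology with a target assortativity and
degree-correlated natural frequencies."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from ..bands import Band
from ..connectivity import BinaryNetwork
from ..topology import assortativity as newman_assortativity


def _as_binary(graph: nx.Graph) -> BinaryNetwork:
    adj = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes()), dtype=int)
    return BinaryNetwork(adj, 1.0, [str(i) for i in sorted(graph.nodes())])


def graph_assortativity(graph: nx.Graph) -> float | None:
    return newman_assortativity(_as_binary(graph))


def rewire_to_assortativity(graph: nx.Graph, target: float, seed: int = 0,
                            tol: float = 0.05,
                            max_swaps: int = 20000) -> tuple[nx.Graph, float, bool]:
    """Degree-preserving double-edge swaps accepted when they move the
    assortativity toward ``target``.

    Returns (graph, achieved assortativity, converged flag). Raises when the
    coefficient is undefined (regular graph).
    """
    g = graph.copy()
    current = graph_assortativity(g)
    if current is None:
        raise ValueError("assortativity undefined (regular graph); cannot rewire")
    rng = np.random.default_rng(seed)
    best = current
    for _ in range(max_swaps):
        if abs(best - target) <= tol:
            return g, best, True
        edges = list(g.edges())
        (a, b), (c, d) = (edges[i] for i in rng.choice(len(edges), 2, replace=False))
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edges_from([(a, b), (c, d)])
        g.add_edges_from([(a, d), (c, b)])
        trial = graph_assortativity(g)
        if trial is not None and abs(trial - target) < abs(best - target):
            best = trial
        else:
            g.remove_edges_from([(a, d), (c, b)])
            g.add_edges_from([(a, b), (c, d)])
    return g, best, abs(best - target) <= tol


def build_network(n: int, model: str = "scale_free", target_assortativity: float = -0.3,
                  seed: int = 0, m: int = 3, p: float = 0.1,
                  tol: float = 0.05, max_swaps: int = 20000) -> nx.Graph:
    """Random graph rewired toward a target assortativity.

    ``model`` is ``scale_free`` (Barabasi-Albert, parameter ``m``) or
    ``erdos_renyi`` (parameter ``p``). The result carries
    ``graph.graph["assortativity"]`` and ``graph.graph["assortativity_converged"]``.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if not -0.9 <= target_assortativity <= 0.9:
        raise ValueError("target assortativity outside [-0.9, 0.9]")
    if model == "scale_free":
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    elif model == "erdos_renyi":
        g = nx.erdos_renyi_graph(n, p, seed=seed)
        # keep the giant component wiring usable: reject degree-0 nodes by
        # attaching them to a random neighbor
        rng = np.random.default_rng(seed)
        for node in list(g.nodes()):
            if g.degree(node) == 0:
                other = int(rng.integers(n))
                while other == node:
                    other = int(rng.integers(n))
                g.add_edge(node, other)
    else:
        raise ValueError(f"unknown model {model!r}")
    g, achieved, converged = rewire_to_assortativity(
        g, target_assortativity, seed=seed, tol=tol, max_swaps=max_swaps)
    g.graph["assortativity"] = achieved
    g.graph["assortativity_converged"] = converged
    return g


def assign_frequencies(graph: nx.Graph, band: Band, rho: float = 0.0,
                       spread: float | None = None, seed: int = 0) -> np.ndarray:
    """Natural frequencies (rad/s) with a planted degree-frequency Spearman.

    Gaussian-copula construction: normal scores of the degree ranks are mixed
    with independent noise at the Pearson level 2*sin(pi*rho/6) so that the
    population Spearman equals ``rho``; uniform marginals are mapped onto the
    band (or a ``spread``-Hz slice centered in the band). ``rho = 0`` gives
    independent draws; ``|rho| = 1`` is comonotone in degree rank.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho outside [-1, 1]")
    nodes = sorted(graph.nodes())
    deg = np.array([graph.degree(v) for v in nodes], dtype=float)
    n = deg.size
    if np.ptp(deg) == 0 and rho != 0:
        raise ValueError("degenerate degree sequence: cannot plant a correlation")
    rng = np.random.default_rng(seed)
    # random tie-break keeps z_deg continuous
    order = np.lexsort((rng.random(n), deg))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    z_deg = stats.norm.ppf(ranks / (n + 1))
    r_pearson = 2.0 * np.sin(np.pi * rho / 6.0)
    z = r_pearson * z_deg + np.sqrt(max(1.0 - r_pearson ** 2, 0.0)) * rng.standard_normal(n)
    u = stats.norm.cdf(z)
    if spread is None:
        lo, hi = band.lo, band.hi
    else:
        lo = max(band.lo, band.center - spread / 2.0)
        hi = min(band.hi, band.center + spread / 2.0)
    f_hz = lo + u * (hi - lo)
    return 2.0 * np.pi * f_hz
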