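"""Phase-oscillator dynamics on a fixed graph.

    dtheta_i/dt = omega_i + sigma_i * sum_j a_ij sin(theta_j - theta_i)

with sigma_i = sigma (uniform) or sigma * |omega_i| / k_i (degree-scaled,
the construction under which the suppressive rule was derived). Integration
is stochastic Heun with optional white phase noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class OscillatorNetwork:
    """Adjacency, natural frequencies (rad/s), and coupling specification."""

    adjacency: np.ndarray
    omega: np.ndarray
    sigma: float
    coupling_mode: str = "uniform"

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("non-finite natural frequencies")
        if self.coupling_mode not in {"uniform", "degree_scaled"}:
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.coupling_mode == "degree_scaled" and (self.degrees < 1).any():
            raise ValueError("degree_scaled coupling requires every k_i >= 1")

    @property
    def n(self) -> int:
        return self.omega.size

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def node_coupling(self) -> np.ndarray:
        if self.coupling_mode == "degree_scaled":
            return self.sigma * np.abs(self.omega) / self.degrees
        return np.full(self.n, self.sigma)

    @classmethod
    def from_graph(cls, graph: nx.Graph, omega: np.ndarray, sigma: float,
                   coupling_mode: str = "uniform") -> "OscillatorNetwork":
        adj = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes()))
        return cls(adj, omega, sigma, coupling_mode)


def _drift(theta: np.ndarray, omega: np.ndarray, sigma_i: np.ndarray,
           adjacency: np.ndarray) -> np.ndarray:
    # sum_j a_ij sin(theta_j - theta_i) = Im(e^{-i theta_i} * (A @ e^{i theta}))_i
    z = np.exp(1j * theta)
    return omega + sigma_i * np.imag(np.conj(z) * (adjacency @ z))


def simulate_kuramoto(network: OscillatorNetwork, duration: float, dt: float = 1e-3,
                      phase_noise: float = 0.0, seed: int = 0,
                      transient: float = 0.0,
                      theta0: np.ndarray | None = None,
                      store_every: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Integrate and return (times, phases) with phases shaped (n, n_stored).

    The first ``transient`` seconds are simulated but not stored. Raises when
    the step is too coarse for the fastest oscillator or phases blow up.
    """
    omega = network.omega
    max_w = np.max(np.abs(omega)) if omega.size else 0.0
    if max_w > 0 and dt > 2.0 * np.pi / (10.0 * max_w):
        raise ValueError(f"dt={dt} too coarse for max |omega| {max_w:.3g} rad/s")
    sigma_i = network.node_coupling()
    adj = network.adjacency
    rng = np.random.default_rng(seed)
    theta = (rng.uniform(0, 2 * np.pi, network.n)
             if theta0 is None else np.array(theta0, dtype=float))

    n_tr = int(round(transient / dt))
    n_keep = int(round(duration / dt))
    noise_amp = phase_noise * np.sqrt(dt)
    stored = []
    times = []
    for step in range(n_tr + n_keep):
        f0 = _drift(theta, omega, sigma_i, adj)
        eta = noise_amp * rng.standard_normal(network.n) if phase_noise > 0 else 0.0
        pred = theta + dt * f0 + eta
        f1 = _drift(pred, omega, sigma_i, adj)
        theta = theta + 0.5 * dt * (f0 + f1) + eta
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError("phases diverged (NaN/inf)")
        # uniform storage grid whose last sample is the exact final state
        if step >= n_tr and (step - n_tr + 1) % store_every == 0:
            stored.append(theta.copy())
            times.append((step - n_tr + 1) * dt)
    return np.array(times), np.array(stored).T


def order_parameter_series(phases: np.ndarray) -> np.ndarray:
    """|mean_j e^{i theta_j}| at each stored time; phases shaped (n, t)."""
    return np.abs(np.exp(1j * phases).mean(axis=0))
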