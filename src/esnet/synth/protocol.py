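"""Anesthesia-session emulator.

Piecewise-stationary Kuramoto dynamics: each concentration step c uses
coupling sigma0 * max(1 - c, sigma_floor) — the floor keeps a trace of
graph-structured coupling at peak dose so the functional network still
reflects the anatomical topology — a frequency spread widening with c, and a
degree-frequency Spearman ramping from 0 at c = 0 to the planted value at
c = 1. The responsiveness model (sigmoid of c with a hysteresis offset) is
deliberately simple plumbing, not an empirical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..bands import ALPHA, Band
from ..session.annotation import SessionAnnotation
from ..session.types import Recording
from .kuramoto import OscillatorNetwork, simulate_kuramoto
from .network import assign_frequencies, build_network
from .render import render_recording


@dataclass
class SessionProtocol:
    """Configuration for one synthetic session."""

    schedule: list[tuple[float, float]]          # (t_s, c) breakpoints
    duration: float
    band: Band = field(default_factory=lambda: ALPHA)
    planted_deg_freq_rho: float = 0.9
    target_assortativity: float = -0.3
    noise_snr: float = 10.0
    seed: int = 0
    n_channels: int = 64
    rate: float = 500.0
    sigma0: float = 3.0
    sigma_floor: float = 0.25   # fraction of sigma0 retained at c = 1
    spread_min: float = 1.0
    spread_max: float | None = None               # None = full band width
    phase_noise: float = 0.5
    dt: float = 1e-3
    model: str = "scale_free"

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("empty concentration schedule")
        for _, c in self.schedule:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"concentration {c} outside [0, 1]")
        if abs(self.planted_deg_freq_rho) > 1:
            raise ValueError("planted rho outside [-1, 1]")


def _responsiveness(schedule_c: np.ndarray, on_thr: float = 0.55,
                    off_thr: float = 0.45, slope: float = 0.03) -> np.ndarray:
    """Sigmoid of c with hysteresis: the threshold drops once unresponsive."""
    resp = np.empty_like(schedule_c)
    unresponsive = False
    for i, c in enumerate(schedule_c):
        thr = off_thr if unresponsive else on_thr
        r = 1.0 / (1.0 + np.exp((c - thr) / slope))
        resp[i] = r
        unresponsive = r < 0.5
    return resp


def _session_frequencies(z_deg: np.ndarray, eps: np.ndarray, band: Band,
                         rho_target: float, c: float,
                         spread_min: float, spread_max: float) -> np.ndarray:
    """Frequencies (rad/s) for one concentration step, from shared latents."""
    rho_c = c * rho_target
    r_p = 2.0 * np.sin(np.pi * rho_c / 6.0)
    z = r_p * z_deg + np.sqrt(max(1.0 - r_p ** 2, 0.0)) * eps
    u = stats.norm.cdf(z)
    spread = spread_min + c * (spread_max - spread_min)
    lo = max(band.lo, band.center - spread / 2.0)
    hi = min(band.hi, band.center + spread / 2.0)
    return 2.0 * np.pi * (lo + u * (hi - lo))


def simulate_session(protocol: SessionProtocol
                     ) -> tuple[Recording, SessionAnnotation, dict]:
    """Simulate one session; returns (Recording, SessionAnnotation, ground truth).

    LOC/ROC are derived from the 30-s responsiveness trace; if the schedule
    never crosses the unresponsiveness threshold they are None and the
    ground-truth dict carries ``"loc_defined": False``.
    """
    p = protocol
    rng = np.random.default_rng(p.seed)
    graph = build_network(p.n_channels, p.model, p.target_assortativity,
                          seed=p.seed)
    deg = np.array([graph.degree(v) for v in sorted(graph.nodes())], dtype=float)
    n = deg.size
    order = np.lexsort((rng.random(n), deg))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    z_deg = stats.norm.ppf(ranks / (n + 1))
    eps = rng.standard_normal(n)
    spread_max = p.spread_max if p.spread_max is not None else p.band.width

    # piecewise-stationary integration, phases continuous across steps
    breakpoints = sorted(p.schedule)
    seg_bounds = [t for t, _ in breakpoints] + [p.duration]
    store_every = max(int(round(1.0 / (p.rate * p.dt))), 1)
    theta = rng.uniform(0, 2 * np.pi, n)
    all_times: list[np.ndarray] = []
    all_phases: list[np.ndarray] = []
    truth_steps = []
    t_offset = 0.0
    for (t0, c), t1 in zip(breakpoints, seg_bounds[1:]):
        if t1 <= t0:
            continue
        omega = _session_frequencies(z_deg, eps, p.band, p.planted_deg_freq_rho,
                                     c, p.spread_min, spread_max)
        sigma_c = p.sigma0 * max(1.0 - c, p.sigma_floor)
        net = OscillatorNetwork.from_graph(graph, omega, sigma_c)
        times, phases = simulate_kuramoto(
            net, duration=t1 - t0, dt=p.dt, phase_noise=p.phase_noise,
            seed=p.seed + 1 + len(truth_steps), theta0=theta,
            store_every=store_every)
        theta = phases[:, -1]  # exact final state, by storage convention
        all_times.append(times + t_offset)
        all_phases.append(phases)
        truth_steps.append({"t0": t0, "t1": t1, "c": c,
                            "rho_c": c * p.planted_deg_freq_rho,
                            "sigma": sigma_c,
                            "omega_hz": (omega / (2 * np.pi)).tolist()})
        t_offset = all_times[-1][-1]

    times = np.concatenate(all_times)
    phases = np.concatenate(all_phases, axis=1)
    net_any = OscillatorNetwork.from_graph(graph, 2 * np.pi * np.full(n, p.band.hi), 1.0)
    recording = render_recording(times - times[0], phases, net_any, p.rate,
                                 amplitudes=1.0, noise_snr=p.noise_snr,
                                 seed=p.seed + 10_000)

    resp_t = np.arange(0.0, p.duration, 30.0)
    c_at = np.array([_schedule_value(breakpoints, t) for t in resp_t])
    resp = _responsiveness(c_at)
    loc = roc = None
    for t, r in zip(resp_t, resp):
        if loc is None and r < 0.5:
            loc = float(t)
        elif loc is not None and roc is None and r >= 0.5:
            roc = float(t)
    annotation = SessionAnnotation(
        concentration=breakpoints,
        responsiveness=list(zip(resp_t.tolist(), resp.tolist())),
        loc_time=loc, roc_time=roc, duration=p.duration,
    )
    truth = {
        "seed": p.seed,
        "planted_deg_freq_rho": p.planted_deg_freq_rho,
        "target_assortativity": p.target_assortativity,
        "achieved_assortativity": graph.graph.get("assortativity"),
        "degrees": deg.tolist(),
        "steps": truth_steps,
        "loc_defined": loc is not None,
    }
    return recording, annotation, truth


def _schedule_value(breakpoints: list[tuple[float, float]], t: float) -> float:
    value = breakpoints[0][1]
    for bt, c in breakpoints:
        if t >= bt:
            value = c
        else:
            break
    return value
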