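"""The anesthesia-adapted local suppressive rule and suppression strength.

For a connected pair (i, j) with normalized frequency difference Y_ij, local
order parameters r_i, r_j (mean WPLI over each node's neighbors) and coupling
lambda = 1 - c (c = rescaled anesthetic concentration):

    s_ij = Y_ij - lambda * (r_i + r_j)
    e_ij = 1 if s_ij > 0 (suppressive) else 0 (synchronizable)

Node strength S_i is the suppressed fraction of i's edges, S_r the suppressed
fraction of a region's edges, and the global S the mean of S_i over nodes of
degree >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .connectivity import BinaryNetwork, WPLIMatrix, bandpass, threshold_proportional, wpli
from .session.annotation import SessionAnnotation
from .session.artifacts import flag_artifacts
from .session.types import REGIONS, Recording
from .spectral import frequency_difference_matrix, peak_frequency


@dataclass
class LocalOrderParameters:
    """Per-node mean WPLI over neighbors; NaN for isolated nodes."""

    r: np.ndarray


@dataclass
class SuppressionResult:
    s_edge: np.ndarray | None = None      # (m,) margins, edge order of net.edges()
    e_edge: np.ndarray | None = None      # (m,) 0/1 statuses
    s_node: np.ndarray | None = None      # (n,) S_i, NaN for isolated nodes
    s_region: dict[str, float] = field(default_factory=dict)
    s_global: float | None = None
    lam: float | None = None
    c: float | None = None


def concentration_to_coupling(c: float) -> float:
    """lambda = 1 - c for rescaled concentration c in [0, 1]."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"concentration {c} outside [0, 1]")
    return 1.0 - c


def local_order_parameters(w: WPLIMatrix, net: BinaryNetwork) -> LocalOrderParameters:
    """r_i = mean WPLI over the neighbors of i; isolated nodes get NaN."""
    adj = net.adjacency
    deg = adj.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (adj * w.values).sum(axis=1) / deg
    r = np.where(deg > 0, r, np.nan)
    return LocalOrderParameters(r)


def edge_suppression(y: np.ndarray, r: LocalOrderParameters, lam: float,
                     net: BinaryNetwork, c: float | None = None) -> SuppressionResult:
    """Evaluate the rule on every connected pair.

    ``y`` is the full symmetric matrix of normalized frequency differences.
    """
    edges = net.edges()
    yi = y[edges[:, 0], edges[:, 1]]
    ri = r.r[edges[:, 0]]
    rj = r.r[edges[:, 1]]
    if np.isnan(yi).any() or np.isnan(ri).any() or np.isnan(rj).any():
        raise ValueError("missing Y or r on an edge endpoint")
    s = yi - lam * (ri + rj)
    e = (s > 0).astype(int)
    return SuppressionResult(s_edge=s, e_edge=e, lam=lam, c=c)


def suppression_strength(result: SuppressionResult, net: BinaryNetwork,
                         regions: list[str],
                         region_rule: str = "either") -> SuppressionResult:
    """Aggregate edge statuses into S_i, S_r, and global S.

    ``region_rule`` decides edge membership in a region: "either" endpoint
    (default) or "both" endpoints. Nodes isolated after thresholding are
    excluded (NaN), keeping every S a proportion over defined quantities.
    """
    if result.e_edge is None:
        raise ValueError("edge statuses not computed")
    if region_rule not in {"either", "both"}:
        raise ValueError(f"unknown region_rule {region_rule!r}")
    edges = net.edges()
    e = result.e_edge
    n = net.n_nodes
    deg = net.adjacency.sum(axis=1)

    supp_count = np.zeros(n)
    np.add.at(supp_count, edges[:, 0], e)
    np.add.at(supp_count, edges[:, 1], e)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_node = supp_count / deg
    s_node = np.where(deg > 0, s_node, np.nan)

    regions_arr = np.array(regions)
    s_region: dict[str, float] = {}
    for region in REGIONS:
        in_r = regions_arr == region
        if not in_r.any():
            continue
        a = in_r[edges[:, 0]]
        b = in_r[edges[:, 1]]
        member = (a | b) if region_rule == "either" else (a & b)
        s_region[region] = float(e[member].mean()) if member.any() else np.nan

    s_global = float(np.nanmean(s_node)) if np.isfinite(s_node).any() else np.nan
    return SuppressionResult(
        s_edge=result.s_edge, e_edge=e, s_node=s_node, s_region=s_region,
        s_global=s_global, lam=result.lam, c=result.c,
    )


def dominant_region(s_region: dict[str, float]) -> str | None:
    """Region with the largest S_r; ties resolve in fixed region order."""
    best, best_val = None, -np.inf
    for region in REGIONS:
        val = s_region.get(region)
        if val is not None and np.isfinite(val) and val > best_val:
            best, best_val = region, val
    return best


@dataclass
class TimecourseWindow:
    t_start: float
    t_end: float
    c: float
    lam: float
    s_global: float
    s_region: dict[str, float]
    dominant: str | None
    flagged: bool
    wpli: WPLIMatrix | None = None
    network: BinaryNetwork | None = None
    peaks: np.ndarray | None = None


def suppression_timecourse(recording: Recording, annotation: SessionAnnotation,
                           config: AnalysisConfig | None = None,
                           keep_details: bool = False) -> list[TimecourseWindow]:
    """Windowed suppression strength across a whole session.

    The recording is band-passed once; non-overlapping windows (default
    10 s) each get their own WPLI (within-window segments only), thresholded
    network, peak map, local order parameters and lambda from c(window
    midpoint). Artifact-flagged windows yield NaN rows.
    """
    cfg = config or AnalysisConfig()
    filtered = bandpass(recording, cfg.band)
    win = cfg.window_sec
    n_win = int(filtered.duration // win)
    if n_win == 0:
        raise ValueError("recording shorter than one window")
    windows = [filtered.slice_time(k * win, (k + 1) * win) for k in range(n_win)]
    flags = flag_artifacts(windows, cfg.artifact_factor)
    regions = recording.regions()

    out: list[TimecourseWindow] = []
    for k, (w_rec, flagged) in enumerate(zip(windows, flags)):
        t0, t1 = k * win, (k + 1) * win
        c = annotation.concentration_at(0.5 * (t0 + t1))
        lam = concentration_to_coupling(c)
        if flagged:
            out.append(TimecourseWindow(t0, t1, c, lam, np.nan, {}, None, True))
            continue
        w = wpli([w_rec], cfg.band, cfg.seg_sec, cfg.seg_overlap_sec)
        net = threshold_proportional(w, cfg.threshold_fraction)
        peaks = peak_frequency(w_rec, cfg.band, cfg.seg_sec, cfg.seg_overlap_sec)
        y = frequency_difference_matrix(peaks)
        r = local_order_parameters(w, net)
        res = edge_suppression(y, r, lam, net, c=c)
        res = suppression_strength(res, net, regions, cfg.region_rule)
        out.append(TimecourseWindow(
            t0, t1, c, lam, res.s_global, res.s_region,
            dominant_region(res.s_region), False,
            wpli=w if keep_details else None,
            network=net if keep_details else None,
            peaks=peaks.peak if keep_details else None,
        ))
    return out
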