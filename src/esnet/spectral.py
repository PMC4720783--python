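"""Peak-frequency maps, normalized frequency differences, and the
degree-frequency correlation with permutation significance."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .bands import Band
from .connectivity import BinaryNetwork
from .session.types import Recording


@dataclass
class PeakFrequencyMap:
    """Per-channel spectral peak (Hz) within a band; NaN flags zero power."""

    peak: np.ndarray
    band: Band
    channel_names: list[str]
    label: str = ""


def peak_frequency(epoch: Recording, band: Band, seg_len: float = 5.0,
                   seg_overlap: float = 1.0) -> PeakFrequencyMap:
    """Welch PSD (Hann segments) per channel; peak = in-band bin of max power.

    Ties at the maximum resolve to the lowest frequency. Channels with zero
    in-band power are flagged NaN.
    """
    rate = epoch.rate
    nper = int(round(seg_len * rate))
    if epoch.n_samples < nper:
        raise ValueError("epoch shorter than one spectral segment")
    if band.hi >= rate / 2.0:
        raise ValueError("band extends beyond Nyquist")
    freqs, psd = signal.welch(epoch.samples, fs=rate, window="hann",
                              nperseg=nper, noverlap=int(round(seg_overlap * rate)),
                              axis=1)
    in_band = (freqs >= band.lo) & (freqs <= band.hi)
    fb = freqs[in_band]
    pb = psd[:, in_band]
    peaks = fb[np.argmax(pb, axis=1)]  # argmax returns first (lowest-f) max
    peaks = np.where(pb.sum(axis=1) > 0, peaks, np.nan)
    return PeakFrequencyMap(peaks, band, list(epoch.channel_names))


def state_peak_frequency(epochs: list[Recording], band: Band,
                         seg_len: float = 5.0, seg_overlap: float = 1.0,
                         label: str = "") -> PeakFrequencyMap:
    """State-level peak: the mean of per-epoch peaks, never a pooled spectrum."""
    if not epochs:
        raise ValueError("no epochs supplied")
    per_epoch = np.stack([peak_frequency(e, band, seg_len, seg_overlap).peak
                          for e in epochs])
    return PeakFrequencyMap(per_epoch.mean(axis=0), band,
                            list(epochs[0].channel_names), label)


def frequency_difference(f_i: float, f_j: float) -> float:
    """Normalized difference |f_i - f_j| / (|f_i| + |f_j|), in [0, 1)."""
    denom = abs(f_i) + abs(f_j)
    if denom == 0:
        raise ValueError("frequency difference undefined for f_i = f_j = 0")
    return abs(f_i - f_j) / denom


def frequency_difference_matrix(pf: PeakFrequencyMap) -> np.ndarray:
    """Symmetric matrix of pairwise normalized frequency differences."""
    f = np.asarray(pf.peak, dtype=float)
    denom = np.abs(f)[:, None] + np.abs(f)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.abs(f[:, None] - f[None, :]) / denom
    y[denom == 0] = np.nan
    np.fill_diagonal(y, 0.0)
    return y


def network_frequency_difference(pf: PeakFrequencyMap, net: BinaryNetwork) -> float:
    """Mean normalized frequency difference over connected pairs."""
    edges = net.edges()
    if len(edges) == 0:
        raise ValueError("network has no edges")
    y = frequency_difference_matrix(pf)
    return float(np.nanmean(y[edges[:, 0], edges[:, 1]]))


def _spearman(x_rank: np.ndarray, y_rank: np.ndarray) -> float:
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / denom)


def degree_frequency_correlation(degrees: np.ndarray, peaks: np.ndarray,
                                 n_perm: int = 10000,
                                 seed: int = 0) -> tuple[float, float]:
    """Spearman rho between node degree and peak frequency, permutation p.

    Mid-rank ties; two-sided p from permuting the frequency vector — exact
    enumeration for n <= 8, seeded Monte-Carlo otherwise. Raises on constant
    inputs, where rho is undefined.
    """
    degrees = np.asarray(degrees, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    n = degrees.size
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if np.ptp(degrees) == 0 or np.ptp(peaks) == 0:
        raise ValueError("constant degrees or peaks: correlation undefined")

    d_rank = stats.rankdata(degrees)
    p_rank = stats.rankdata(peaks)
    rho = _spearman(d_rank, p_rank)

    tol = 1e-12
    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(p_rank):
            total += 1
            if abs(_spearman(d_rank, np.array(perm))) >= abs(rho) - tol:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if abs(_spearman(d_rank, rng.permutation(p_rank))) >= abs(rho) - tol:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return rho, p
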