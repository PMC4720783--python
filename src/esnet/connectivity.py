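"""Band-pass filtering, epoching, WPLI estimation, and proportional thresholding.

The weighted phase lag index of a channel pair is

    WPLI = |E{Im C}| / E{|Im C|}

with the expectation taken over Hann-tapered overlapping segments and over
the frequency bins inside the analysis band. Pairs whose imaginary
cross-spectrum is identically zero (e.g. identical signals, pure zero-lag
coupling) get WPLI 0 — exactly the couplings the index is built to discount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import Band
from .session.types import Recording


@dataclass
class WPLIMatrix:
    """Symmetric channel x channel WPLI in [0, 1], zero diagonal."""

    values: np.ndarray
    channel_names: list[str]
    n_segments: int
    band: Band

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("WPLI matrix must be square")


@dataclass
class BinaryNetwork:
    """Thresholded undirected adjacency (0/1, zero diagonal)."""

    adjacency: np.ndarray
    threshold_fraction: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> np.ndarray:
        """Upper-triangle edge list as an (m, 2) index array."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu] == 1
        return np.column_stack([iu[0][mask], iu[1][mask]])


def design_bandpass(band: Band, rate: float) -> np.ndarray:
    """Zero-phase-ready FIR band-pass taps (applied with filtfilt)."""
    nyq = rate / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band hi {band.hi} Hz at or above Nyquist {nyq} Hz")
    transition = min(2.0, band.lo / 2.0)
    numtaps = int(3.3 * rate / transition)
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    return signal.firwin(numtaps, [band.lo, band.hi], pass_zero=False, fs=rate)


def bandpass(recording: Recording, band: Band) -> Recording:
    """Zero-phase band-pass of the whole recording."""
    taps = design_bandpass(band, recording.rate)
    padlen = min(3 * len(taps), recording.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], recording.samples, axis=1, padlen=padlen)
    return Recording(filtered, recording.rate, list(recording.channel_names),
                     dict(recording.montage))


def epoch(recording: Recording, epoch_len: float = 10.0,
          overlap: float = 0.0) -> list[Recording]:
    """Slice into fixed-length epochs; the trailing partial epoch is dropped."""
    n_len = int(round(epoch_len * recording.rate))
    n_step = int(round((epoch_len - overlap) * recording.rate))
    if n_step <= 0:
        raise ValueError("overlap must be smaller than epoch length")
    if recording.n_samples < n_len:
        raise ValueError("recording shorter than one epoch")
    out = []
    for start in range(0, recording.n_samples - n_len + 1, n_step):
        out.append(Recording(recording.samples[:, start:start + n_len],
                             recording.rate, list(recording.channel_names),
                             dict(recording.montage)))
    return out


def bandpass_epoch(recording: Recording, band: Band, epoch_len: float = 10.0,
                   overlap: float = 0.0) -> list[Recording]:
    """Filter the full recording, then epoch it."""
    return epoch(bandpass(recording, band), epoch_len, overlap)


def _segment_ffts(samples: np.ndarray, rate: float, seg_len: float,
                  seg_overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered segment rFFTs: (n_segments, n_channels, n_bins), freqs."""
    nper = int(round(seg_len * rate))
    step = int(round((seg_len - seg_overlap) * rate))
    if step <= 0:
        raise ValueError("segment overlap must be smaller than segment length")
    n_samp = samples.shape[1]
    if n_samp < nper:
        return np.empty((0, samples.shape[0], nper // 2 + 1)), np.fft.rfftfreq(nper, 1 / rate)
    window = signal.get_window("hann", nper)
    starts = range(0, n_samp - nper + 1, step)
    segs = np.stack([samples[:, s:s + nper] * window for s in starts])
    return np.fft.rfft(segs, axis=2), np.fft.rfftfreq(nper, 1 / rate)


def wpli(epochs: list[Recording], band: Band, seg_len: float = 5.0,
         seg_overlap: float = 1.0) -> WPLIMatrix:
    """WPLI with the expectation pooled over all segments of all epochs.

    Per-epoch networks are obtained by passing a single epoch; state-level
    networks by passing every retained epoch of the state.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    rate = epochs[0].rate
    if any(e.rate != rate for e in epochs):
        raise ValueError("sampling-rate mismatch across epochs")
    n_ch = epochs[0].n_channels

    num = np.zeros((n_ch, n_ch))
    den = np.zeros((n_ch, n_ch))
    n_segments = 0
    for ep in epochs:
        Z, freqs = _segment_ffts(ep.samples, rate, seg_len, seg_overlap)
        in_band = (freqs >= band.lo) & (freqs <= band.hi)
        if not in_band.any():
            raise ValueError("no frequency bins inside the band")
        Zb = Z[:, :, in_band]
        for seg in Zb:  # seg: (n_ch, n_bins)
            cross = seg[:, None, :] * np.conj(seg[None, :, :])
            im = cross.imag.copy()
            # identical/zero-lag pairs have Im C = 0 analytically; rounding
            # noise at ~1e-16 of |C| must not masquerade as phase lag
            im[np.abs(im) < 1e-12 * np.abs(cross)] = 0.0
            num += im.sum(axis=2)
            den += np.abs(im).sum(axis=2)
            n_segments += 1
    if n_segments < 2:
        raise ValueError("need at least 2 spectral segments for the expectation")

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.abs(num) / den
    values[den == 0] = 0.0
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # exact symmetry against rounding
    return WPLIMatrix(values, list(epochs[0].channel_names), n_segments, band)


def threshold_proportional(w: WPLIMatrix, fraction: float = 0.3) -> BinaryNetwork:
    """Keep the floor(fraction * n(n-1)/2) strongest pairs as edges.

    Ties at the cutoff are broken by lexicographic (i, j) order, so the
    result is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    values = w.values
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k = int(np.floor(fraction * len(iu)))
    order = np.lexsort((ju, iu, -values[iu, ju]))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    return BinaryNetwork(adj, fraction, list(w.channel_names))


def global_wpli(w: WPLIMatrix, net: BinaryNetwork) -> float:
    """Mean WPLI over the connected pairs of the binary network."""
    edges = net.edges()
    if len(edges) == 0:
        raise ValueError("network has no edges")
    return float(w.values[edges[:, 0], edges[:, 1]].mean())
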