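"""Amplitude-based artifact flagging for epochs.

Replaces manual visual inspection with a deterministic heuristic: an epoch
is flagged when any channel's peak-to-peak amplitude exceeds a configurable
multiple of that channel's median peak-to-peak across epochs. Flagged epochs
are excluded from averages, never deleted.
"""

from __future__ import annotations

import numpy as np

from .types import Recording


def flag_artifacts(epochs: list[Recording], factor: float = 8.0) -> np.ndarray:
    """Boolean flag per epoch; True = artifact."""
    if not epochs:
        return np.zeros(0, dtype=bool)
    ptp = np.stack([np.ptp(e.samples, axis=1) for e in epochs])  # (n_epochs, n_ch)
    med = np.median(ptp, axis=0)
    med = np.where(med > 0, med, np.inf)  # silent channels can't trip the flag
    return (ptp > factor * med).any(axis=1)
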