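"""Core recording container and montage validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical scalp regions, in the fixed order used for tie-breaking.
REGIONS = ("prefrontal", "frontal", "central", "temporal", "parietal", "occipital")


@dataclass
class Recording:
    """A multichannel recording: channels x samples, with rate and montage.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (synthetic data uses arbitrary units).
    rate : float
        Sampling rate in samples/s.
    channel_names : list of str
        One label per row of ``samples``.
    montage : dict
        Maps each channel name to one region in :data:`REGIONS`.
    """

    samples: np.ndarray
    rate: float
    channel_names: list[str]
    montage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x samples array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.montage:
            validate_montage(self.montage, self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def regions(self) -> list[str]:
        """Region label per channel, in channel order."""
        return [self.montage[name] for name in self.channel_names]

    def average_reference(self) -> "Recording":
        """Return a copy re-referenced to the instantaneous channel mean."""
        ref = self.samples - self.samples.mean(axis=0, keepdims=True)
        return Recording(ref, self.rate, list(self.channel_names), dict(self.montage))

    def slice_time(self, start: float, end: float) -> "Recording":
        """Extract the half-open time window [start, end) in seconds."""
        i0 = int(round(start * self.rate))
        i1 = int(round(end * self.rate))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError(f"window [{start}, {end}) outside recording")
        return Recording(
            self.samples[:, i0:i1], self.rate, list(self.channel_names), dict(self.montage)
        )


def validate_montage(montage: dict[str, str], channel_names: list[str]) -> None:
    """Check that every channel has exactly one known region."""
    missing = [c for c in channel_names if c not in montage]
    if missing:
        raise ValueError(f"montage missing channels: {missing}")
    bad = {c: r for c, r in montage.items() if c in channel_names and r not in REGIONS}
    if bad:
        raise ValueError(f"unknown regions in montage: {bad}; expected one of {REGIONS}")
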