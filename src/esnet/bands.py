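"""Frequency-band definitions shared by the filtering and spectral stages."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A named frequency band in Hz.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"alpha"``.
    lo, hi : float
        Band edges in Hz; requires ``0 < lo < hi``.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges: lo={self.lo}, hi={self.hi}")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


DELTA = Band("delta", 1.0, 4.0)
THETA = Band("theta", 4.0, 8.0)
ALPHA = Band("alpha", 8.0, 13.0)
BETA = Band("beta", 13.0, 30.0)
BROADBAND = Band("broadband", 1.0, 50.0)

BANDS = {b.name: b for b in (DELTA, THETA, ALPHA, BETA, BROADBAND)}


def get_band(name: str) -> Band:
    """Look up a default band by name."""
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(BANDS)}") from None
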