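"""Session annotations: dose schedule, responsiveness, and state segmentation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np


class StateLabel(str, Enum):
    """The five 5-minute behavioral states around LOC/ROC."""

    BASELINE = "Baseline"
    TRANS_UN = "TransUN"
    UCS = "UCS"
    TRANS_CON = "TransCON"
    RECOVERY = "Recovery"


@dataclass
class SessionAnnotation:
    """Anesthetic schedule and behavioral trace for one session.

    ``concentration`` is a piecewise-constant schedule of (time_s, c)
    breakpoints with c already rescaled to [0, 1] (1 = the session's maximum
    dose). ``responsiveness`` holds (time_s, fraction) pairs sampled every
    30 s. ``loc_time``/``roc_time`` are in seconds from recording start and
    may be None when the subject never became unresponsive.
    """

    concentration: list[tuple[float, float]]
    responsiveness: list[tuple[float, float]]
    loc_time: float | None = None
    roc_time: float | None = None
    duration: float | None = None
    state_windows: dict[StateLabel, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentration = [(float(t), float(c)) for t, c in self.concentration]
        self.responsiveness = [(float(t), float(v)) for t, v in self.responsiveness]
        if not self.concentration:
            raise ValueError("empty concentration schedule")
        for _, c in self.concentration:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"concentration {c} outside [0, 1]")
        if self.loc_time is not None and self.roc_time is not None:
            if not self.loc_time < self.roc_time:
                raise ValueError("loc_time must precede roc_time")

    def concentration_at(self, t: float) -> float:
        """Evaluate the piecewise-constant schedule at time ``t``."""
        times = [bp[0] for bp in self.concentration]
        idx = int(np.searchsorted(times, t, side="right")) - 1
        return self.concentration[max(idx, 0)][1]

    def drug_onset(self) -> float | None:
        """First time the concentration becomes positive, or None."""
        for t, c in self.concentration:
            if c > 0:
                return t
        return None

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionAnnotation":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            concentration=[tuple(p) for p in doc["concentration"]],
            responsiveness=[tuple(p) for p in doc["responsiveness"]],
            loc_time=doc.get("loc"),
            roc_time=doc.get("roc"),
            duration=doc.get("duration"),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "concentration": [list(p) for p in self.concentration],
                    "responsiveness": [list(p) for p in self.responsiveness],
                    "loc": self.loc_time,
                    "roc": self.roc_time,
                    "duration": self.duration,
                },
                fh,
            )


def segment_states(annotation: SessionAnnotation,
                   state_len: float = 300.0) -> dict[StateLabel, tuple[float, float]]:
    """Place the five state windows around LOC/ROC.

    Half-open [start, end) windows in seconds. Baseline is the final
    ``state_len`` of pre-drug data; TransUN ends at LOC; UCS is centered
    between LOC and ROC; TransCON starts at ROC; Recovery is the final
    ``state_len`` of the session. Raises if LOC/ROC are undefined, the
    unconscious period is too short, or any two windows would overlap.
    """
    loc, roc = annotation.loc_time, annotation.roc_time
    if loc is None or roc is None:
        raise ValueError("LOC/ROC undefined: subject never became unresponsive")
    if roc - loc <= state_len:
        raise ValueError(
            f"unconscious period {roc - loc:.0f}s cannot hold a full "
            f"{state_len:.0f}s UCS window"
        )
    onset = annotation.drug_onset()
    if onset is None:
        raise ValueError("no drug onset in the concentration schedule")
    duration = annotation.duration
    if duration is None:
        duration = max(annotation.responsiveness[-1][0] + 30.0, roc + 2 * state_len)

    baseline = (onset - state_len, onset)
    trans_un = (loc - state_len, loc)
    mid = 0.5 * (loc + roc)
    ucs = (mid - state_len / 2.0, mid + state_len / 2.0)
    trans_con = (roc, roc + state_len)
    recovery = (duration - state_len, duration)

    windows = {
        StateLabel.BASELINE: baseline,
        StateLabel.TRANS_UN: trans_un,
        StateLabel.UCS: ucs,
        StateLabel.TRANS_CON: trans_con,
        StateLabel.RECOVERY: recovery,
    }
    for label, (start, end) in windows.items():
        if start < 0 or end > duration:
            raise ValueError(f"{label.value} window [{start:.0f}, {end:.0f}) "
                             "falls outside the session")
    ordered = list(windows.values())
    for (s0, e0), (s1, e1) in zip(ordered, ordered[1:]):
        if e0 > s1:
            raise ValueError("state windows overlap; session too short")
    annotation.state_windows = windows
    return windows


def smooth_responsiveness(trace: np.ndarray, window: float = 300.0,
                          step: float = 30.0) -> np.ndarray:
    """Right-aligned moving average of a per-30-s responsiveness trace.

    Output has one value per input sample; the value at index k averages the
    samples in the window ending at k, shrinking at the left edge.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty responsiveness trace")
    width = max(int(round(window / step)), 1)
    out = np.empty_like(trace)
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    for k in range(trace.size):
        lo = max(0, k - width + 1)
        out[k] = (csum[k + 1] - csum[lo]) / (k + 1 - lo)
    return out
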