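"""Run configuration shared by the orchestration and timecourse stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .bands import ALPHA, Band


@dataclass
class AnalysisConfig:
    band: Band = field(default_factory=lambda: ALPHA)
    threshold_fraction: float = 0.3
    epoch_sec: float = 10.0
    seg_sec: float = 5.0
    seg_overlap_sec: float = 1.0
    window_sec: float = 10.0
    state_len_sec: float = 300.0
    region_rule: str = "either"  # edge belongs to a region via either/both endpoints
    artifact_factor: float = 8.0
    hub_quantile: float = 0.8
    louvain_restarts: int = 10
    n_perm: int = 10000
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = {"name": self.band.name, "lo": self.band.lo, "hi": self.band.hi}
        return d
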