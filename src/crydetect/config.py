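"""Pipeline configuration with provenance hashing.

One flat config object carries every tunable parameter of the pipeline.
Outputs written by the CLI embed the config hash and seed so that mixed
runs are detectable downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    sample_rate: int = 16000
    epoch_seconds: float = 5.0
    frame_seconds: float = 0.025
    hop_seconds: float = 0.010
    smd_threshold: float = 0.5
    sd_ratio_low: float = 0.5
    sd_ratio_high: float = 2.0
    k_folds: int = 5
    seed: int = 7
    start_min_cry: int = 6
    start_window: int = 12
    stop_gap: int = 60
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.epoch_seconds <= 0:
            raise ValueError("sample_rate and epoch_seconds must be positive")
        if not 0 < self.hop_seconds <= self.frame_seconds:
            raise ValueError("need 0 < hop_seconds <= frame_seconds")
        if not 0 < self.sd_ratio_low <= 1.0 <= self.sd_ratio_high:
            raise ValueError("SD ratio bounds must bracket 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not 0 < self.start_min_cry <= self.start_window:
            raise ValueError("need 0 < start_min_cry <= start_window")
        if self.stop_gap <= 0:
            raise ValueError("stop_gap must be positive")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config parameters: {sorted(unknown)}")
        return cls(**raw)
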