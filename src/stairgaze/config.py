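"""Run configuration: every published analysis constant, overridable and
echoed to the run log.  Loadable from YAML or JSON."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .saccades import DetectorConfig


@dataclass(frozen=True)
class RunConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    min_frames: int = 2           # frames a fixation must last (~66 ms at 30 Hz)
    pre_window_s: float = 2.0     # gaze considered from 2 s before the first step
    bin_width_deg: float = 9.0    # direction histogram bins (40 over the circle)
    alpha: float = 0.05
    stride_period_s: float = 0.55  # expected stride period for gait segmentation
    strict_breaks: bool = False
    n_per_group: int = 18
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Stable digest of the full configuration, stamped on outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        det = d.pop("detector", {})
        return cls(detector=DetectorConfig(**det), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)
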