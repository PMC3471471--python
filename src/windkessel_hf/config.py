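"""Pipeline configuration: grid bounds, model constants, estimation mode.

A single nestable key:value file (YAML) holds the defaults; CLI flags
override individual entries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .estimator import ParameterGrid
from .waveform import DEFAULT_INERTANCE, DEFAULT_P_NEXT


@dataclass
class PipelineConfig:
    grid: ParameterGrid = field(default_factory=ParameterGrid)
    inertance: float = DEFAULT_INERTANCE
    p_next: float = DEFAULT_P_NEXT
    bp_mode: str = "fixed_time"
    policy: str = "matched"
    noise_sd: float = 2.0  # mmHg, synthetic-cohort BP measurement noise

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        grid_kwargs = payload.pop("grid", {})
        return cls(grid=ParameterGrid(**grid_kwargs), **payload)
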