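"""Analysis configuration: one place for every tunable threshold.

Defaults match the package's documented conventions (6 Hz zero-phase
low-pass, 5% peak-speed window threshold, 20 mm/s movement floor, 0.2 s gap
interpolation limit).  A YAML/JSON file with a top-level ``analysis``
section (or the bare keys) overrides them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass(frozen=True)
class AnalysisConfig:
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    threshold_fraction: float = 0.05
    speed_floor_mm_s: float = 20.0
    max_gap_interp_s: float = 0.2
    max_nan_fraction: float = 0.10
    degenerate_floor_mm: float = 20.0
    denominator_mode: str = "measured_total"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.filter_cutoff_hz <= 0:
            raise ParameterError("filter_cutoff_hz must be > 0")
        if not 0 <= self.threshold_fraction < 1:
            raise ParameterError("threshold_fraction must be in [0, 1)")
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must be in (0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = data.get("analysis", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
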