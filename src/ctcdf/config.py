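"""Run configuration: every pipeline knob with a documented default.

The configuration round-trips through YAML/JSON; unknown keys are rejected so
that typos fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .channels import NeighborhoodPattern, default_pattern
from .evaluation import DEFAULT_AVG_CELLS_PER_IMAGE, DEFAULT_OVERLAP_THRESHOLD
from .illumination import IlluminationConfig
from .postprocess import DEFAULT_MIN_AREA, DEFAULT_OPENING_RADIUS


@dataclass
class RunConfig:
    # illumination
    wsize: int = 64
    # feature pattern: explicit offsets override the diameter-derived rings
    pattern_diameter_px: float = 40.0
    pattern_offsets: list[list[int]] | None = None
    # boosting
    rounds: int = 200
    seed: int = 0
    neg_pos_ratio: float = 3.0
    max_pos_per_image: int = 2000
    score_threshold: float = 0.0
    # postprocess
    opening_radius: int = DEFAULT_OPENING_RADIUS
    min_area: int = DEFAULT_MIN_AREA
    # evaluation
    avg_cells_per_image: float = DEFAULT_AVG_CELLS_PER_IMAGE
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD

    def illumination(self) -> IlluminationConfig:
        return IlluminationConfig(wsize=self.wsize)

    def pattern(self) -> NeighborhoodPattern:
        if self.pattern_offsets is not None:
            return NeighborhoodPattern(
                offsets=tuple(tuple(o) for o in self.pattern_offsets)
            )
        return default_pattern(self.pattern_diameter_px)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
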