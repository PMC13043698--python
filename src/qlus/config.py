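"""Pipeline configuration: one flat record of every tunable, with defaults
matching the study-faithful analysis (256 grey levels, offset (0, 1),
symmetric GLCM, natural-log entropy, 50 px depth, strict 8-zone aggregation,
p < 0.05). Round-trips through YAML/JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # GLCM settings
    levels: int = 256
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = True
    entropy_base: str = "ln"
    # image I/O
    bit_reduction: str = "floor"
    # ROI settings
    depth_px: int = 50
    depth_mm: float | None = None  # overrides depth_px when pixel spacing known
    min_roi_pixels: int = 100
    # aggregation policy
    aggregation_policy: str = "strict"
    min_zones_lenient: int = 6
    # oxygenation
    percent_scale: bool = True
    # statistics
    ci_method: str = "bootstrap"
    n_resamples: int = 2000
    p_method: str = "t"
    adjust: str | None = None
    group_by_machine: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offset"] = list(self.offset)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "offset" in data:
            data = {**data, "offset": tuple(data["offset"])}
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
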