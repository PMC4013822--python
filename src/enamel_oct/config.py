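"""Pipeline configuration: one dataclass whose defaults are the method's
published constants, loadable from / dumpable to YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import defaults
from .roi import ContourParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    spacing_axial: float = defaults.AXIAL_UM_PER_PX
    spacing_lateral: float = defaults.LATERAL_UM_PER_PX
    spacing_slice: float = defaults.SLICE_UM
    h1: tuple = defaults.H1
    h2: tuple = defaults.H2
    se: tuple = defaults.SE
    h3: tuple = defaults.H3
    shift_range: int = defaults.SHIFT_RANGE_PX
    zoom_percents: tuple = defaults.ZOOM_PERCENTS
    limit_shift_px: int = defaults.LIMIT_SHIFT_PX
    neighbor_window: int = defaults.NEIGHBOR_WINDOW
    poly_degree: int = defaults.POLY_DEGREE
    contour: ContourParams = field(default_factory=ContourParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("h1", "h2", "se", "h3", "zoom_percents"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("h1", "h2", "se", "h3", "zoom_percents"):
            if key in d:
                d[key] = tuple(d[key])
        if "contour" in d and isinstance(d["contour"], dict):
            d["contour"] = ContourParams(**d["contour"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
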