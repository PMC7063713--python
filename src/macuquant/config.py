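"""Pipeline configuration: dataclasses with lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

from .segmentation import DEFAULT_POLARITIES, DEFAULT_TRACE_ORDER


@dataclass
class GeometryConfig:
    central_diameter_mm: float = 0.60
    taz_outer_diameter_mm: float = 2.50
    ring_diameters_mm: Tuple[float, ...] = (0.92, 1.23, 1.55, 1.87, 2.18, 2.50)
    temporal_side_od: str = "left"
    temporal_side_os: str = "right"

    def temporal_side(self, laterality: str) -> str:
        return self.temporal_side_od if laterality == "OD" else self.temporal_side_os


@dataclass
class SegmentationConfig:
    polarities: Tuple[str, ...] = DEFAULT_POLARITIES
    trace_order: Tuple[int, ...] = DEFAULT_TRACE_ORDER
    max_step: int = 2
    min_gap: int = 3
    smoothing_sigma: Tuple[float, float] = (1.0, 3.0)
    reference_axial_length_mm: float = 23.95


@dataclass
class AngioConfig:
    noise_k: float = 2.0
    large_vessel_factor: float = 3.0
    min_vessel_width_um: float = 25.0
    adaptive_window_mm: float = 0.20
    adaptive_offset: float = 3.0
    rcd_numerator: str = "capillary"   # or "all"
    run_faz_detection: bool = True


@dataclass
class StatsConfig:
    alpha_general: float = 0.05
    alpha_family: float = 0.01         # thickness/density multiple-testing level
    positive_group: str = "DON"
    negative_group: str = "control"
    seed: int = 0


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    angio: AngioConfig = field(default_factory=AngioConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            kwargs = dict(sub)
            for f in dataclasses.fields(klass):
                if f.name in kwargs and isinstance(kwargs[f.name], list):
                    kwargs[f.name] = tuple(kwargs[f.name])
            return klass(**kwargs)

        return cls(
            geometry=build(GeometryConfig, d.get("geometry", {})),
            segmentation=build(SegmentationConfig, d.get("segmentation", {})),
            angio=build(AngioConfig, d.get("angio", {})),
            stats=build(StatsConfig, d.get("stats", {})),
        )

    def to_yaml(self, path=None) -> Optional[str]:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d or {})

    def content_hash(self) -> str:
        """Stable hash of the configuration contents."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
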