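"""Structured run configuration shared by the CLI and the analysis drivers."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


def _strict_from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            if f.name in _SECTION_TYPES and isinstance(value, dict):
                value = _strict_from_dict(_SECTION_TYPES[f.name], value)
            kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class SegmentationConfig:
    k: int = 2
    grid_size: int = 4
    threshold: float | None = None  # None -> Otsu
    connectivity: int = 8
    microns_per_pixel: float = 3.0


@dataclass
class GraphConfig:
    mode: str = "deterministic"  # deterministic | exponential | power_law
    threshold_um: float = 65.0
    scale_um: float = 65.0
    exponent: float = 2.0
    strict_less: bool = False


@dataclass
class FeatureConfig:
    exclude_default: bool = True
    spectral: bool = False


@dataclass
class FactorizationConfig:
    rank: int = 2
    n_restarts: int = 3
    tol: float = 1e-9
    max_iter: int = 500


@dataclass
class RunConfig:
    """All stage parameters plus the root seed; round-trips through YAML/JSON."""

    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    factorization: FactorizationConfig = field(default_factory=FactorizationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _strict_from_dict(cls, data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


_SECTION_TYPES = {
    "segmentation": SegmentationConfig,
    "graph": GraphConfig,
    "features": FeatureConfig,
    "factorization": FactorizationConfig,
}
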