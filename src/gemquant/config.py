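"""Run configuration: JSON round-trip with strict key checking.

Defaults are the study's printed analysis parameters: probability threshold
0.5, component size band 5,000–50,000 voxels at the 1.37 nm reference voxel,
particle radius 12.5 nm, proximity cutoff and dilation radius 50 nm, ten
prebleach FRAP frames at 50 ms intervals.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any

from .detect import DetectionParams, PreprocessParams
from .errors import ConfigError
from .spatial import SpatialParams
from .synthetic import ProbMapConfig, SceneConfig

__all__ = ["RunConfig", "dataclass_from_dict", "dataclass_to_dict"]


def dataclass_to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: dataclass_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: dataclass_to_dict(v) for k, v in obj.items()}
    return obj


def dataclass_from_dict(cls, payload: dict, path: str = ""):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config keys at {path or cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in payload.items():
        ftype = fields[name].type
        target = _resolve(cls, ftype)
        if dataclasses.is_dataclass(target) and isinstance(value, dict):
            value = dataclass_from_dict(target, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[name] = value
    return cls(**kwargs)


def _resolve(owner, annotation):
    """Resolve a (possibly string, due to postponed evaluation) annotation."""
    if isinstance(annotation, str):
        import sys

        return sys.modules[owner.__module__].__dict__.get(annotation)
    return annotation


def _default_scene() -> SceneConfig:
    return SceneConfig(
        volume_shape=(160, 160, 120),
        voxel_size=1.37,
        lamella_thickness=140.0,
        structure_kind="plane",
        n_bound=20,
        bound_distance_mean=10.0,
        bound_distance_sd=6.0,
        n_background=10,
        min_separation=34.0,
    )


@dataclass
class RunConfig:
    """End-to-end tomographic pipeline configuration."""

    scene: SceneConfig = field(default_factory=_default_scene)
    probmap: ProbMapConfig = field(default_factory=lambda: ProbMapConfig(blob_radius=16.4))
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    seed: int = 0
    output_dir: str = "results/pipeline"
    verbosity: int = 1

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        text = json.dumps(dataclass_to_dict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "RunConfig":
        if os.path.exists(source):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        return dataclass_from_dict(cls, payload)
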