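"""Run configuration: one YAML file covering every pipeline stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .networks import TrainConfig
from .preprocess import HE2_STAIN_MATRIX
from .tvseg import TVParams

__all__ = ["PreprocessConfig", "RunConfig", "load_config", "config_hash"]


@dataclass
class PreprocessConfig:
    """Stain separation, CLAHE and resolution-policy parameters."""

    stain_matrix: list = field(
        default_factory=lambda: HE2_STAIN_MATRIX.tolist()
    )
    structure_channel: int = 0  # hematoxylin
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    scale: float = 0.5  # classifier-resolution factor


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tv: TVParams = field(default_factory=TVParams)
    training: TrainConfig = field(default_factory=TrainConfig)
    min_area: int = 500
    seed: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _update_dataclass(obj, values: dict):
    fields = {f.name for f in dataclasses.fields(obj)}
    unknown = set(values) - fields
    if unknown:
        raise ValueError(f"unknown config keys for {type(obj).__name__}: {sorted(unknown)}")
    return dataclasses.replace(obj, **values)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a `RunConfig` from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    cfg = RunConfig()
    for section, cls_attr in (("preprocess", "preprocess"), ("tv", "tv"),
                              ("training", "training")):
        if section in data:
            setattr(cfg, cls_attr,
                    _update_dataclass(getattr(cfg, cls_attr), data.pop(section)))
    return _update_dataclass(cfg, data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration (for run manifests)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
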