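"""Pipeline configuration: nested sections mirroring every stage's defaults,
with lossless YAML round-tripping and rejection of unknown keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .blocks import BLOCK_SIZE, P_BLOCKS
from .motion import DIFF_THRESH, RATIO_THRESH, T_TARGET
from .mstmap import MAP_COLS, MAP_ROWS, SCALES

__all__ = ["SelectConfig", "SegmentBankConfig", "BlocksConfig", "MapConfig",
           "ModelConfig", "PipelineConfig"]


@dataclass
class SelectConfig:
    diff_thresh: float = DIFF_THRESH
    ratio_thresh: float = RATIO_THRESH
    t_target: int = T_TARGET


@dataclass
class SegmentBankConfig:
    lambdas: tuple = (4.0, 8.0, 12.0)
    n_orient: int = 8
    bandwidth: float = 1.0
    gamma: float = 0.5
    phi: float = 0.0


@dataclass
class BlocksConfig:
    p: int = P_BLOCKS
    block_size: int = BLOCK_SIZE
    flip_axis: bool = False   # set when the finger root is on the right


@dataclass
class MapConfig:
    scales: tuple = SCALES
    out_rows: int = MAP_ROWS
    out_cols: int = MAP_COLS


@dataclass
class ModelConfig:
    arch: str = "light_vit"       # light_vit | light_vit_reduced | baselines
    input_size: int = 224
    num_classes: int = 2


@dataclass
class PipelineConfig:
    select: SelectConfig = field(default_factory=SelectConfig)
    segment: SegmentBankConfig = field(default_factory=SegmentBankConfig)
    blocks: BlocksConfig = field(default_factory=BlocksConfig)
    map: MapConfig = field(default_factory=MapConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    out_dir: str = "veinlive_out"

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, context="pipeline")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _build(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: "
                         f"{sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = fields[name].default_factory() \
            if fields[name].default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default):
            kwargs[name] = _build(type(default), value or {}, context=name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)
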