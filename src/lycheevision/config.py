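"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .status import StatusThresholds

__all__ = ["PipelineConfig"]


@dataclass
class ClaheConfig:
    enabled: bool = True
    blocks: int = 10
    clip_limit: float = 0.015


@dataclass
class MorphConfig:
    erode_r: int = 3
    dilate_r: int = 3


@dataclass
class SplitConfig:
    smooth_win: int = 9
    min_prominence: float = 2.0


@dataclass
class GateConfig:
    lo: int = 800
    hi: int = 1700


@dataclass
class EvalConfig:
    iou: float = 0.4


@dataclass
class PipelineConfig:
    clahe: ClaheConfig = field(default_factory=ClaheConfig)
    morph: MorphConfig = field(default_factory=MorphConfig)
    status: StatusThresholds = field(default_factory=StatusThresholds)
    split: SplitConfig = field(default_factory=SplitConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            clahe=ClaheConfig(**d.get("clahe", {})),
            morph=MorphConfig(**d.get("morph", {})),
            status=StatusThresholds(**d.get("status", {})),
            split=SplitConfig(**d.get("split", {})),
            gate=GateConfig(**d.get("gate", {})),
            eval=EvalConfig(**d.get("eval", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
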