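"""Pipeline configuration: one block per stage, strict keys, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RoiConfig", "DetectConfig", "SegmentConfig", "StainConfig", "ScoreConfig", "PipelineConfig"]


@dataclass
class RoiConfig:
    tile_size: int = 256
    overlap_threshold: float = 0.5


@dataclass
class DetectConfig:
    min_distance: int = 6
    prominence: float = 0.15
    sigma: float = 1.5
    match_radius: float = 5.0


@dataclass
class SegmentConfig:
    dilation_radius: float = 3.0
    od_threshold: float = 0.1
    sigma: float = 0.5


@dataclass
class StainConfig:
    dab_od_threshold: float = 0.15


@dataclass
class ScoreConfig:
    m: float = 0.06
    k: int = 3000
    t: float = 0.1
    cutoffs: list[float] = field(default_factory=lambda: [5.0, 50.0])
    min_cells: int | None = None


_BLOCKS = {
    "roi": RoiConfig,
    "detect": DetectConfig,
    "segment": SegmentConfig,
    "stain": StainConfig,
    "score": ScoreConfig,
}


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """All stage parameters plus the seed and output directory.

    Unknown keys are rejected on parse; ``parse(serialize(c)) == c``.
    """

    roi: RoiConfig = field(default_factory=RoiConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    stain: StainConfig = field(default_factory=StainConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    rng_seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for name, block_cls in _BLOCKS.items():
            kwargs[name] = _build(block_cls, data.pop(name, {}) or {})
        kwargs["rng_seed"] = int(data.pop("rng_seed", 0))
        kwargs["output_dir"] = data.pop("output_dir", None)
        if data:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(data)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})
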