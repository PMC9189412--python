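"""Pipeline configuration: every tunable constant in one serializable place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .autolabel import AutolabelParams
from .types import CANONICAL_HEIGHT, CANONICAL_WIDTH

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All thresholds of the labeling/relabeling/evaluation pipeline.

    Defaults are the operating point of the original counting system:
    h-minima depth 3, region area 1,000-5,000 px, MER ratio 1-2.5,
    canonical frame 256 x 1,021, 80/20 split, relabel confidence cut 0.75,
    NMS IoU 0.6, match IoU 0.5.
    """

    autolabel: AutolabelParams = field(default_factory=AutolabelParams)
    canonical_size: tuple[int, int] = (CANONICAL_WIDTH, CANONICAL_HEIGHT)
    roi_pad: int = 20
    train_fraction: float = 0.8
    split_seed: int = 0
    confidence_threshold: float = 0.75
    nms_iou: float = 0.6
    match_iou: float = 0.5

    def __post_init__(self) -> None:
        for name, v in (
            ("train_fraction", self.train_fraction),
            ("confidence_threshold", self.confidence_threshold),
            ("nms_iou", self.nms_iou),
            ("match_iou", self.match_iou),
        ):
            if not (0.0 < v < 1.0 or (name == "confidence_threshold" and v in (0.0, 1.0))):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.roi_pad < 0:
            raise ValueError("roi_pad must be non-negative")
        w, h = self.canonical_size
        if w < 1 or h < 1:
            raise ValueError("canonical size must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["autolabel"]["bilateral"] = list(d["autolabel"]["bilateral"])
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        auto = d.pop("autolabel", {})
        if "bilateral" in auto:
            auto["bilateral"] = tuple(auto["bilateral"])
        d["autolabel"] = AutolabelParams(**auto)
        d["canonical_size"] = tuple(d.get("canonical_size", (CANONICAL_WIDTH, CANONICAL_HEIGHT)))
        return cls(**d)
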