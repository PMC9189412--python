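"""Detector interface and the two implementations shipped with the package.

The relabeling and evaluation stages only need "canonical image -> scored
boxes".  Any trained model can be plugged in behind
:class:`DetectorInterface`; the package ships

* :class:`WatershedDetector` — the unsupervised labeler wrapped as a
  detector (every box scored 1.0), and
* :class:`OracleDetector` — returns supplied ground-truth boxes, used to
  exercise the relabel/eval plumbing in tests.
"""

from __future__ import annotations

from typing import Mapping, Protocol, Sequence

from .autolabel import AutolabelParams, autolabel_image
from .types import Box, CanonicalImage, Detection

__all__ = ["DetectorInterface", "WatershedDetector", "OracleDetector"]


class DetectorInterface(Protocol):
    def detect(self, img: CanonicalImage) -> list[Detection]: ...


class WatershedDetector:
    """The Cb-watershed autolabeler as a detector; all scores are 1.0."""

    def __init__(self, params: AutolabelParams | None = None) -> None:
        self.params = params or AutolabelParams()

    def detect(self, img: CanonicalImage) -> list[Detection]:
        ann = autolabel_image(img, self.params)
        return [Detection(box=b, score=1.0) for b in ann.boxes]


class OracleDetector:
    """Replays known ground-truth boxes keyed by image id."""

    def __init__(
        self, boxes_by_id: Mapping[str, Sequence[Box]], score: float = 1.0
    ) -> None:
        self.boxes_by_id = dict(boxes_by_id)
        self.score = score

    def detect(self, img: CanonicalImage) -> list[Detection]:
        boxes = self.boxes_by_id.get(img.source_id, [])
        return [Detection(box=b, score=self.score) for b in boxes]
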