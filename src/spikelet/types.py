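"""Core domain types shared across the pipeline.

Coordinate convention: row-major rasters, 0-based indices, and half-open
axis-aligned rectangles — a :class:`Box` with ``(x, y, w, h)`` covers pixel
columns ``x .. x+w-1`` and rows ``y .. y+h-1``.  The Pascal-VOC on-disk
dialect (1-based inclusive) is converted at the XML boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Box",
    "RawImage",
    "CanonicalImage",
    "GrayImage",
    "SpikeMask",
    "CandidateRegion",
    "Annotation",
    "Detection",
    "CANONICAL_WIDTH",
    "CANONICAL_HEIGHT",
]

#: Canonical working frame every spike photo is resampled to (width, height).
CANONICAL_WIDTH = 256
CANONICAL_HEIGHT = 1021


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, 0-based, half-open.

    ``x``/``y`` locate the upper-left pixel; ``w``/``h`` are the side lengths
    in pixels.  This is the in-memory form of the "minimum enclosed
    rectangle" saved for each candidate spikelet region.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")

    @property
    def x2(self) -> int:
        """Exclusive right edge."""
        return self.x + self.w

    @property
    def y2(self) -> int:
        """Exclusive bottom edge."""
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def aspect_ratio(self) -> float:
        """Long side over short side (orientation-free, >= 1)."""
        return max(self.w, self.h) / min(self.w, self.h)

    def contains(self, other: "Box") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and self.x2 >= other.x2
            and self.y2 >= other.y2
        )


def _require_uint8(pixels: np.ndarray, ndim: int, what: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != ndim:
        raise ValueError(f"{what}: expected {ndim}-d array, got {arr.ndim}-d")
    if arr.dtype != np.uint8:
        raise ValueError(f"{what}: expected uint8 pixels, got {arr.dtype}")
    if ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"{what}: expected 3 channels, got {arr.shape[2]}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{what}: empty raster")
    return arr


@dataclass
class RawImage:
    """A captured spike photo: 8-bit RGB raster plus identity metadata."""

    pixels: np.ndarray
    image_id: str = ""
    wheat_line: str = ""

    def __post_init__(self) -> None:
        self.pixels = _require_uint8(self.pixels, 3, "RawImage")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CanonicalImage:
    """An ROI crop resampled to the fixed canonical frame.

    ``roi_offset`` is the (row, col) origin of the crop in the raw frame and
    ``scale`` the (row, col) resampling factors, so canonical coordinates can
    be mapped back to the original photo.
    """

    pixels: np.ndarray
    source_id: str = ""
    wheat_line: str = ""
    roi_offset: tuple[int, int] = (0, 0)
    scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = _require_uint8(self.pixels, 3, "CanonicalImage")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """Single-channel 8-bit raster derived from a canonical image."""

    pixels: np.ndarray
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = _require_uint8(self.pixels, 2, "GrayImage")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SpikeMask:
    """Binary spike-vs-board mask (1 = spike) with the Otsu cut used."""

    pixels: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("SpikeMask: expected 2-d array")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("SpikeMask: values must be exactly 0/1")
        self.pixels = arr.astype(np.uint8)
        if not (0 <= int(self.threshold_used) <= 255):
            raise ValueError("SpikeMask: threshold outside [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class CandidateRegion:
    """One watershed basin: its label, pixel count, and tight bounding box."""

    label_id: int
    area: int
    box: Box

    def __post_init__(self) -> None:
        if self.label_id < 1:
            raise ValueError("label_id must be >= 1")
        if self.area < 1:
            raise ValueError("area must be >= 1")


@dataclass
class Annotation:
    """Per-image set of spikelet boxes with provenance.

    ``source`` tracks the two-round labeling loop: ``watershed`` for the
    unsupervised initial labels, ``dcnn`` for detector relabels, and
    ``corrected`` after manual edits.
    """

    image_id: str
    wheat_line: str
    image_size: tuple[int, int]  # (width, height)
    boxes: list[Box] = field(default_factory=list)
    source: str = "watershed"

    _SOURCES = ("watershed", "dcnn", "corrected")

    def __post_init__(self) -> None:
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        w, h = self.image_size
        for i, b in enumerate(self.boxes):
            if b.x < 0 or b.y < 0 or b.x2 > w or b.y2 > h:
                raise ValueError(
                    f"box {i} {b} outside image of size {self.image_size}"
                )

    def with_boxes(self, boxes: Sequence[Box], source: str) -> "Annotation":
        return replace(self, boxes=list(boxes), source=source)


@dataclass(frozen=True)
class Detection:
    """A scored box produced by a detector."""

    box: Box
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
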