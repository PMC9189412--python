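"""Annotation I/O and dataset bookkeeping.

Boxes live on disk in Pascal-VOC XML (1-based inclusive ``xmin/ymin/
xmax/ymax``) and in memory as 0-based half-open :class:`~spikelet.types.Box`
rectangles; the conversion happens only in :func:`write_voc_xml` /
:func:`read_voc_xml` so the off-by-one has exactly one home:

    xmin = x + 1,  ymin = y + 1,  xmax = x + w,  ymax = y + h

The module also implements the dataset mechanics of the two-round labeling
loop: per-line train/validation splits, the strict >0.75 confidence cut for
detector relabels, logged manual-correction edits, and per-line/per-split
spikelet count tables.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import Annotation, Box, Detection

__all__ = [
    "write_voc_xml",
    "read_voc_xml",
    "DatasetSplit",
    "split_dataset",
    "filter_by_confidence",
    "apply_corrections",
    "summarize_counts",
    "count_table_from_cells",
]

DEFAULT_CONFIDENCE_THRESHOLD = 0.75


def write_voc_xml(ann: Annotation, path: str | Path) -> Path:
    """Write one annotation as a Pascal-VOC XML file."""
    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = ann.image_id
    src = ET.SubElement(root, "source")
    ET.SubElement(src, "database").text = ann.source
    ET.SubElement(src, "wheat_line").text = ann.wheat_line
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.image_size[0])
    ET.SubElement(size, "height").text = str(ann.image_size[1])
    ET.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = "spikelet"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(b.x + 1)
        ET.SubElement(bb, "ymin").text = str(b.y + 1)
        ET.SubElement(bb, "xmax").text = str(b.x + b.w)
        ET.SubElement(bb, "ymax").text = str(b.y + b.h)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")
    return path


def read_voc_xml(path: str | Path) -> Annotation:
    """Parse a Pascal-VOC XML file; inverse of :func:`write_voc_xml`."""
    root = ET.parse(path).getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise ValueError(f"{path}: missing size element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    src = root.find("source")
    source = (src.findtext("database") if src is not None else None) or "watershed"
    if source not in Annotation._SOURCES:
        source = "watershed"
    wheat_line = (src.findtext("wheat_line") if src is not None else "") or ""
    boxes: list[Box] = []
    for i, obj in enumerate(root.iter("object")):
        bb = obj.find("bndbox")
        if bb is None:
            raise ValueError(f"{path}: object {i} has no bndbox")
        xmin, ymin = int(bb.findtext("xmin")), int(bb.findtext("ymin"))
        xmax, ymax = int(bb.findtext("xmax")), int(bb.findtext("ymax"))
        if xmax < xmin or ymax < ymin:
            raise ValueError(f"{path}: object {i} has malformed box")
        box = Box(x=xmin - 1, y=ymin - 1, w=xmax - xmin + 1, h=ymax - ymin + 1)
        if box.x < 0 or box.y < 0 or box.x2 > width or box.y2 > height:
            raise ValueError(f"{path}: object {i} outside image bounds")
        boxes.append(box)
    return Annotation(
        image_id=root.findtext("filename") or "",
        wheat_line=wheat_line,
        image_size=(width, height),
        boxes=boxes,
        source=source,
    )


@dataclass
class DatasetSplit:
    """Seeded per-line train/validation partition of annotated images."""

    train: list[Annotation]
    validation: list[Annotation]
    test_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [a.image_id for a in self.train] + [a.image_id for a in self.validation]
        seen: set[str] = set()
        for i in ids + list(self.test_ids):
            if i in seen:
                raise ValueError(f"image id {i!r} appears in more than one split")
            seen.add(i)


def split_dataset(
    anns: Sequence[Annotation], train_fraction: float, seed: int
) -> DatasetSplit:
    """Per-wheat-line seeded random split into train and validation.

    Within each line, a seeded uniform permutation assigns
    ``floor(train_fraction * n)`` images to training and the rest to
    validation (e.g. 100 images at 0.8 -> 80 train / 20 validation).
    Deterministic for a given seed.
    """
    if not anns:
        raise ValueError("empty annotation list")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[Annotation] = []
    validation: list[Annotation] = []
    by_line: dict[str, list[Annotation]] = {}
    for a in anns:
        by_line.setdefault(a.wheat_line, []).append(a)
    for line in sorted(by_line):
        group = sorted(by_line[line], key=lambda a: a.image_id)
        n_train = int(np.floor(train_fraction * len(group)))
        order = rng.permutation(len(group))
        train.extend(group[i] for i in order[:n_train])
        validation.extend(group[i] for i in order[n_train:])
    return DatasetSplit(train=train, validation=validation, seed=seed)


def filter_by_confidence(
    dets: Sequence[Detection], threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> list[Detection]:
    """Keep detections whose score is strictly above the threshold.

    The cut is strict ("higher than 0.75"): a score of exactly 0.75 is
    dropped.  Input order is preserved.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return [d for d in dets if d.score > threshold]


def apply_corrections(
    ann: Annotation, removals: Sequence[int] = (), additions: Sequence[Box] = ()
) -> Annotation:
    """Manual-correction edit: drop boxes by index, append new ones.

    Keeping corrections as explicit (removals, additions) edit lists makes a
    corrected dataset reproducible from the machine labels plus the edit
    log.  The result carries ``source='corrected'``.
    """
    removals = list(removals)
    if len(set(removals)) != len(removals):
        raise ValueError("duplicate removal index")
    for i in removals:
        if not (0 <= i < len(ann.boxes)):
            raise ValueError(f"removal index {i} out of range [0, {len(ann.boxes)})")
    kept = [b for i, b in enumerate(ann.boxes) if i not in set(removals)]
    return ann.with_boxes(kept + list(additions), source="corrected")


def summarize_counts(
    anns_by_split: Mapping[str, Iterable[Annotation]]
) -> pd.DataFrame:
    """Labeled-spikelet counts per (wheat line, split) with SUM margins.

    ``anns_by_split`` maps a split name (e.g. ``training``/``validation``)
    to its annotations.  Cells are total box counts; the ``SUM`` row and
    column are the corresponding marginal totals.
    """
    splits = list(anns_by_split)
    lines: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    for split, anns in anns_by_split.items():
        for a in anns:
            if a.wheat_line not in lines:
                lines.append(a.wheat_line)
            key = (a.wheat_line, split)
            counts[key] = counts.get(key, 0) + len(a.boxes)
    cells = {
        split: [counts.get((line, split), 0) for line in lines] for split in splits
    }
    return count_table_from_cells(lines, cells)


def count_table_from_cells(
    lines: Sequence[str], cells: Mapping[str, Sequence[int]]
) -> pd.DataFrame:
    """Build the margin-totalled count table from per-line cell counts."""
    table = pd.DataFrame(dict(cells), index=list(lines), dtype=int)
    table["SUM"] = table.sum(axis=1)
    table.loc["SUM"] = table.sum(axis=0)
    table.index.name = "wheat_line"
    return table
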