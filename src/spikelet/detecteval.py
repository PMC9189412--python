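"""Detection scoring: IoU, greedy TP/FP/FN matching, PR/AP, and NMS.

A detection is a true positive when its IoU with an unmatched ground-truth
box is at least the matching threshold (0.5 by convention); otherwise it is
a false positive, and every unmatched ground truth is a false negative.
From the match counts,

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)

and AP@0.5IOU is the area under the precision-recall curve swept over
detection scores, using all-point interpolation with the monotone precision
envelope.  Non-maximum suppression greedily keeps the highest-scored box
and discards overlaps above its own IoU threshold (0.6 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import Box, Detection

__all__ = [
    "iou",
    "MatchResult",
    "match_detections",
    "precision_recall",
    "PRCurve",
    "average_precision",
    "nms",
]

DEFAULT_MATCH_IOU = 0.5
DEFAULT_NMS_IOU = 0.6


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN counts plus the matched (detection, gt, IoU) pairs."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tp != len(self.matched_pairs):
            raise ValueError("TP must equal the number of matched pairs")


def _by_descending_score(dets: Sequence[Detection]) -> list[int]:
    # stable: ties keep input order
    return sorted(range(len(dets)), key=lambda i: -dets[i].score)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[Box],
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> MatchResult:
    """Greedy score-ordered matching of detections to ground-truth boxes.

    Detections are processed by descending score; each claims the unmatched
    ground truth of highest IoU if that IoU >= ``iou_threshold`` (TP), else
    it is an FP.  Ground truths left unclaimed are FNs.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must be in (0, 1)")
    taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    fp = 0
    for di in _by_descending_score(dets):
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(dets[di].box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            pairs.append((di, best_j, best_iou))
        else:
            fp += 1
    return MatchResult(
        tp=len(pairs), fp=fp, fn=len(gts) - len(pairs), matched_pairs=pairs
    )


def precision_recall(m: MatchResult) -> tuple[float, float, bool]:
    """(precision, recall, degenerate_flag) from a match result.

    Zero denominators yield 0 and raise the flag instead of an error, so
    empty images do not abort a batch evaluation.
    """
    degenerate = (m.tp + m.fp == 0) or (m.tp + m.fn == 0)
    precision = m.tp / (m.tp + m.fp) if m.tp + m.fp > 0 else 0.0
    recall = m.tp / (m.tp + m.fn) if m.tp + m.fn > 0 else 0.0
    return precision, recall, degenerate


@dataclass
class PRCurve:
    """Precision-recall sweep points and the resulting average precision."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float


def average_precision(
    dets_per_image: Sequence[Sequence[Detection]],
    gts_per_image: Sequence[Sequence[Box]],
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> PRCurve:
    """AP at a fixed IoU threshold over a set of images.

    Detections from all images are pooled and swept by descending score
    (ties by input order); each detection greedily matches the best
    unmatched ground truth *of its own image*.  Cumulative TP/FP counts
    give the PR points; the precision monotone envelope is integrated over
    recall (all-point interpolation).
    """
    if len(dets_per_image) != len(gts_per_image):
        raise ValueError("detections and ground truths must pair per image")
    n_gt = sum(len(g) for g in gts_per_image)
    if n_gt == 0:
        raise ValueError("no ground truth boxes")
    pool: list[tuple[float, int, int]] = []  # (score, image, det index)
    for img, dets in enumerate(dets_per_image):
        for k, d in enumerate(dets):
            pool.append((d.score, img, k))
    order = sorted(range(len(pool)), key=lambda i: (-pool[i][0], pool[i][1], pool[i][2]))
    taken = [[False] * len(g) for g in gts_per_image]
    tps = np.zeros(len(pool), dtype=bool)
    for rank, i in enumerate(order):
        _, img, k = pool[i]
        det = dets_per_image[img][k]
        gts = gts_per_image[img]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[img][j]:
                continue
            v = iou(det.box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[img][best_j] = True
            tps[rank] = True
    if len(pool) == 0:
        return PRCurve(np.zeros(0), np.zeros(0), 0.0)
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone envelope: p_env(r) = max precision at recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate(([0.0], recall[:-1]))
    ap = float(np.sum((recall - r_prev) * envelope))
    return PRCurve(recall=recall, precision=precision, ap=ap)


def nms(
    dets: Sequence[Detection], iou_threshold: float = DEFAULT_NMS_IOU
) -> list[Detection]:
    """Greedy non-maximum suppression.

    Accept detections by descending score; a candidate overlapping an
    already-accepted box with IoU strictly above ``iou_threshold`` is
    suppressed.  No two survivors mutually exceed the threshold.
    """
    survivors: list[Detection] = []
    for i in _by_descending_score(dets):
        d = dets[i]
        if all(iou(d.box, s.box) <= iou_threshold for s in survivors):
            survivors.append(d)
    return survivors
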