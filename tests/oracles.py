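"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized/cumulative code paths:
the Otsu oracle evaluates all 256 candidate thresholds one by one, the AP
oracle re-runs greedy matching from scratch at every score cutoff and
integrates the precision envelope over the resulting points, and the count
statistics are plain Python loops.
"""

from __future__ import annotations

import math

import numpy as np

from spikelet.detecteval import iou


def otsu_brute_force(pixels: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization; smallest t on ties."""
    flat = pixels.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    if best_t is None:
        raise ValueError("constant image")
    return best_t


def _match_prefix(dets_sorted, gts_per_image, iou_threshold):
    """Greedy matching of a score-ordered pooled detection list."""
    taken = [[False] * len(g) for g in gts_per_image]
    tp = fp = 0
    for img, box in dets_sorted:
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts_per_image[img]):
            if taken[img][j]:
                continue
            v = iou(box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[img][best_j] = True
            tp += 1
        else:
            fp += 1
    return tp, fp


def ap_brute_force(dets_per_image, gts_per_image, iou_threshold=0.5) -> float:
    """AP by enumerating every score cutoff and integrating the envelope.

    For each cutoff, matching is recomputed from scratch on the retained
    detections; the (recall, precision) points are then combined with the
    monotone precision envelope and integrated stepwise over recall.
    """
    n_gt = sum(len(g) for g in gts_per_image)
    pool = []
    for img, dets in enumerate(dets_per_image):
        for d in dets:
            pool.append((d.score, img, d.box))
    # stable descending-score order, ties by insertion
    pool = sorted(pool, key=lambda t: -t[0])
    points = []  # (recall, precision) per cutoff = per prefix length
    for k in range(1, len(pool) + 1):
        prefix = [(img, box) for (_, img, box) in pool[:k]]
        tp, fp = _match_prefix(prefix, gts_per_image, iou_threshold)
        points.append((tp / n_gt, tp / (tp + fp)))
    if not points:
        return 0.0
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        p_env = max(p for (rr, p) in points if rr >= r)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def rmse_loop(t, d) -> float:
    acc = 0.0
    for ti, di in zip(t, d):
        acc += (ti - di) ** 2
    return math.sqrt(acc / len(t))


def rrmse_loop(t, d) -> float:
    acc = 0.0
    for ti, di in zip(t, d):
        acc += ((ti - di) / ti) ** 2
    return math.sqrt(acc / len(t))


def r2_loop(t, d) -> float:
    tbar = sum(t) / len(t)
    num = sum((ti - di) ** 2 for ti, di in zip(t, d))
    den = sum((ti - tbar) ** 2 for ti in t)
    return 1.0 - num / den
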