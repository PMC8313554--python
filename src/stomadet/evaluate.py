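"""Detection scoring: overlap-based precision/recall and single-class mAP@0.5.

Two matching modes reflect two validation protocols:

* ``overlap`` -- a detection is correct when its box overlaps a stoma at all
  (IoU > 0), the formalization of visual inspection of overlaid boxes;
* ``iou50`` -- the standard benchmark criterion, IoU >= 0.5.

Matching is greedy and one-to-one in descending score order (largest IoU
first among unmatched ground truths); duplicate detections of an
already-matched stoma count as false positives.  Set-level precision/recall
are the mean +/- sd of per-image values, matching how per-population
accuracies are reported for this assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BoundingBox, Detection
from .stitch import iou as box_iou

__all__ = ["EvalResult", "match_detections", "precision_recall", "mean_average_precision"]

MODES = ("overlap", "iou50")


@dataclass
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision_mean: float
    precision_sd: float
    recall_mean: float
    recall_sd: float
    per_image: list[dict] = field(default_factory=list)


def match_detections(
    detections: list[Detection], gt_boxes: list[BoundingBox], mode: str = "overlap"
) -> tuple[list[bool], list[bool]]:
    """Greedy one-to-one matching; returns per-detection TP flags, per-gt matched flags."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; valid: {MODES}")
    min_iou = 0.5 if mode == "iou50" else 0.0
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score, detections[i].box.x_min, detections[i].box.y_min),
    )
    tp_flags = [False] * len(detections)
    gt_matched = [False] * len(gt_boxes)
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, gb in enumerate(gt_boxes):
            if gt_matched[j]:
                continue
            v = box_iou(detections[i].box, gb)
            if v > best_iou:
                best_iou = v
                best_j = j
        ok = best_j >= 0 and (mode == "overlap" or best_iou >= min_iou)
        if ok:
            tp_flags[i] = True
            gt_matched[best_j] = True
    return tp_flags, gt_matched


def precision_recall(
    per_image: list[tuple[list[Detection], list[BoundingBox]]], mode: str = "overlap"
) -> EvalResult:
    """Per-image precision/recall aggregated as mean +/- sd across images.

    An image with neither detections nor ground truth scores 1.0 on both
    metrics, so blank negatives do not poison set means.
    """
    if not per_image:
        raise ValueError("need at least one image")
    rows = []
    tp_total = fp_total = fn_total = 0
    for idx, (dets, gts) in enumerate(per_image):
        tp_flags, gt_matched = match_detections(dets, gts, mode)
        tp = sum(tp_flags)
        fp = len(dets) - tp
        fn = len(gts) - sum(gt_matched)
        precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
        rows.append(
            {"image": idx, "tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
        )
        tp_total += tp
        fp_total += fp
        fn_total += fn
    p = np.array([r["precision"] for r in rows])
    r = np.array([r["recall"] for r in rows])
    return EvalResult(
        true_positives=tp_total,
        false_positives=fp_total,
        false_negatives=fn_total,
        precision_mean=float(p.mean()),
        precision_sd=float(p.std(ddof=1)) if len(rows) > 1 else 0.0,
        recall_mean=float(r.mean()),
        recall_sd=float(r.std(ddof=1)) if len(rows) > 1 else 0.0,
        per_image=rows,
    )


def mean_average_precision(
    per_image: list[tuple[list[Detection], list[BoundingBox]]], iou: float = 0.5
) -> float | None:
    """Single-class average precision at the given IoU threshold.

    Detections from all images are ranked by score; the precision-recall
    staircase is integrated with all-point interpolation.  Returns None when
    there is no ground truth at all (AP undefined).
    """
    n_gt = sum(len(gts) for _, gts in per_image)
    if n_gt == 0:
        return None
    records = []  # (score, tiebreak, is_tp)
    for img_idx, (dets, gts) in enumerate(per_image):
        matched = [False] * len(gts)
        order = sorted(
            range(len(dets)),
            key=lambda i: (-dets[i].score, dets[i].box.x_min, dets[i].box.y_min),
        )
        for i in order:
            best_j, best_v = -1, 0.0
            for j, gb in enumerate(gts):
                if matched[j]:
                    continue
                v = box_iou(dets[i].box, gb)
                if v > best_v:
                    best_v, best_j = v, j
            is_tp = best_j >= 0 and best_v >= iou
            if is_tp:
                matched[best_j] = True
            records.append((dets[i].score, img_idx, is_tp))
    if not records:
        return 0.0
    records.sort(key=lambda t: (-t[0], t[1]))
    tps = np.cumsum([1 if tp else 0 for _, _, tp in records])
    fps = np.cumsum([0 if tp else 1 for _, _, tp in records])
    recall = tps / n_gt
    precision = tps / (tps + fps)
    # all-point interpolation: precision envelope from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    recall = np.concatenate([[0.0], recall])
    prec_env = np.concatenate([[prec_env[0] if prec_env.size else 0.0], prec_env])
    return float(np.sum(np.diff(recall) * prec_env[1:]))
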