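"""Anchor-to-ground-truth matching and box-offset encoding.

An anchor is positive when its IoU with some ground-truth box reaches the
match threshold; additionally each ground-truth box's single best anchor is
forced positive so that no annotated stoma is left without a training signal.
Positive anchors carry normalized center/size regression targets:

    dx = (g_cx - a_cx) / a_w     dw = log(g_w / a_w)
    dy = (g_cy - a_cy) / a_h     dh = log(g_h / a_h)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import AnchorGrid

__all__ = ["MatchResult", "match_anchors", "encode_boxes", "decode_offsets", "iou_matrix"]


@dataclass
class MatchResult:
    labels: np.ndarray      # (N,) int8: 1 positive, 0 negative
    gt_index: np.ndarray    # (N,) int64: matched gt for positives, -1 otherwise
    targets: np.ndarray     # (N, 4) float64 offsets, zero rows for negatives

    @property
    def n_matched(self) -> int:
        return int(self.labels.sum())

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (A, 4) and (B, 4) corner arrays (half-open boxes)."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def encode_boxes(gt_corners: np.ndarray, anchors: AnchorGrid, idx: np.ndarray) -> np.ndarray:
    """Offsets for anchors ``idx`` regressing onto their assigned gt corners."""
    g = np.asarray(gt_corners, dtype=float)
    gw = g[:, 2] - g[:, 0]
    gh = g[:, 3] - g[:, 1]
    gcx = (g[:, 0] + g[:, 2]) / 2
    gcy = (g[:, 1] + g[:, 3]) / 2
    return np.stack(
        [
            (gcx - anchors.cx[idx]) / anchors.w[idx],
            (gcy - anchors.cy[idx]) / anchors.h[idx],
            np.log(gw / anchors.w[idx]),
            np.log(gh / anchors.h[idx]),
        ],
        axis=1,
    )


def decode_offsets(offsets: np.ndarray, anchors: AnchorGrid) -> np.ndarray:
    """Inverse of :func:`encode_boxes`: offsets for every anchor -> corner array."""
    o = np.asarray(offsets, dtype=float)
    cx = anchors.cx + o[:, 0] * anchors.w
    cy = anchors.cy + o[:, 1] * anchors.h
    w = anchors.w * np.exp(np.clip(o[:, 2], -4, 4))
    h = anchors.h * np.exp(np.clip(o[:, 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def match_anchors(
    gt_boxes: np.ndarray | list, anchors: AnchorGrid, match_iou: float = 0.5
) -> MatchResult:
    """Label every anchor against the ground truth of one tile.

    ``gt_boxes`` may be a list of :class:`~stomadet.io.BoundingBox` or an
    (G, 4) corner array.  With no ground truth every anchor is negative and
    ``n_matched`` is zero.
    """
    if not 0.0 < match_iou < 1.0:
        raise ValueError("match_iou must lie in (0, 1)")
    n = anchors.n_anchors
    labels = np.zeros(n, dtype=np.int8)
    gt_index = np.full(n, -1, dtype=np.int64)
    targets = np.zeros((n, 4), dtype=float)

    if hasattr(gt_boxes, "__len__") and len(gt_boxes) == 0:
        return MatchResult(labels, gt_index, targets)
    if not isinstance(gt_boxes, np.ndarray):
        gt = np.array([b.as_tuple() if hasattr(b, "as_tuple") else b for b in gt_boxes], float)
    else:
        gt = gt_boxes.astype(float).reshape(-1, 4)

    iou = iou_matrix(gt, anchors.corners)  # (G, N)
    best_gt = iou.argmax(axis=0)
    best_iou = iou.max(axis=0)
    pos = best_iou >= match_iou
    # best-match forcing: every gt claims its best not-yet-claimed anchor, so
    # two gts whose argmax collides still both end up with a positive anchor
    claimed: set[int] = set()
    for gi in np.argsort(-iou.max(axis=1), kind="stable"):
        order = np.argsort(-iou[gi], kind="stable")
        for a in order:
            if a not in claimed:
                claimed.add(int(a))
                pos[a] = True
                best_gt[a] = gi
                break

    labels[pos] = 1
    gt_index[pos] = best_gt[pos]
    idx = np.flatnonzero(pos)
    targets[idx] = encode_boxes(gt[best_gt[idx]], anchors, idx)
    return MatchResult(labels, gt_index, targets)
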