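"""Detection loss: softmax classification + smooth-L1 localization.

    L = (L_c + alpha * L_l) / N

where N is the number of matched (positive) anchors, L_c is softmax
cross-entropy over {background, stoma} summed over the positives plus the
hardest negatives (mined at a fixed negatives:positives ratio), and L_l is
smooth-L1 between predicted and target offsets summed over positive anchors.
When N = 0 the loss is defined as 0 (the batch carries no training signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matching import MatchResult

__all__ = ["LossBreakdown", "smooth_l1", "compute_loss", "loss_and_gradients"]


@dataclass
class LossBreakdown:
    total: float
    classification: float
    localization: float
    n_matched: int


def smooth_l1(residual: np.ndarray) -> np.ndarray:
    """Elementwise smooth-L1: 0.5 r^2 for |r| < 1, |r| - 0.5 otherwise."""
    r = np.abs(np.asarray(residual, dtype=float))
    return np.where(r < 1.0, 0.5 * r * r, r - 0.5)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _select_anchors(
    class_logits: np.ndarray, match: MatchResult, neg_pos_ratio: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of positives and of the mined hard negatives."""
    pos = match.positive_indices
    neg_candidates = np.flatnonzero(match.labels == 0)
    n_neg = min(neg_pos_ratio * pos.size, neg_candidates.size)
    if n_neg == 0:
        return pos, np.empty(0, dtype=np.int64)
    # hardness of a negative = its cross-entropy as background = -log p(bg)
    logp = _log_softmax(class_logits[neg_candidates])
    hardness = -logp[:, 0]
    order = np.argsort(-hardness, kind="stable")[:n_neg]
    return pos, neg_candidates[order]


def compute_loss(
    class_logits: np.ndarray,
    box_offsets: np.ndarray,
    match: MatchResult,
    alpha: float = 1.0,
    neg_pos_ratio: int = 3,
) -> LossBreakdown:
    """Loss for one tile's predictions against its match result."""
    breakdown, _, _ = loss_and_gradients(
        class_logits, box_offsets, match, alpha=alpha, neg_pos_ratio=neg_pos_ratio
    )
    return breakdown


def loss_and_gradients(
    class_logits: np.ndarray,
    box_offsets: np.ndarray,
    match: MatchResult,
    alpha: float = 1.0,
    neg_pos_ratio: int = 3,
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. the class logits and box offsets.

    Gradients have the full (N, 2) / (N, 4) anchor shape with zeros at
    unselected anchors, ready to backpropagate through a linear head.
    """
    logits = np.asarray(class_logits, dtype=float)
    offsets = np.asarray(box_offsets, dtype=float)
    n_anchors = match.labels.size
    if logits.shape != (n_anchors, 2):
        raise ValueError(f"class logits shape {logits.shape} != ({n_anchors}, 2)")
    if offsets.shape != (n_anchors, 4):
        raise ValueError(f"box offsets shape {offsets.shape} != ({n_anchors}, 4)")

    grad_logits = np.zeros_like(logits)
    grad_offsets = np.zeros_like(offsets)
    n = match.n_matched
    if n == 0:
        return LossBreakdown(0.0, 0.0, 0.0, 0), grad_logits, grad_offsets

    pos, neg = _select_anchors(logits, match, neg_pos_ratio)
    selected = np.concatenate([pos, neg])
    classes = np.concatenate([np.ones(pos.size, np.int64), np.zeros(neg.size, np.int64)])

    logp = _log_softmax(logits[selected])
    l_c = float(-logp[np.arange(selected.size), classes].sum())
    p = np.exp(logp)
    p[np.arange(selected.size), classes] -= 1.0
    grad_logits[selected] = p / n

    residual = offsets[pos] - match.targets[pos]
    l_l = float(smooth_l1(residual).sum())
    grad_offsets[pos] = alpha * np.clip(residual, -1.0, 1.0) / n

    total = (l_c + alpha * l_l) / n
    return LossBreakdown(total, l_c, l_l, n), grad_logits, grad_offsets
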