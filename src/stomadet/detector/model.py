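"""Trainable anchor head, training loop and tile prediction.

The head is convolutional in structure: every grid cell shares one linear map
from the cell's feature vector to, per anchor shape, two class logits and four
box offsets.  Training minimizes ``L = (L_c + alpha L_l)/N`` plus an L2
penalty with RMSprop-with-momentum under a staircase-decayed learning rate
(``lr(step) = initial * decay^(step div decay_steps)``), evaluates validation
mAP@0.5 on a fixed schedule, keeps only improving checkpoints and stops early
after a patience budget of evaluations without improvement.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..io import BoundingBox, Detection
from .anchors import DEFAULT_ANCHOR_CONFIG, AnchorConfig, AnchorGrid, build_anchors
from .features import FeatureConfig, extract_features
from .loss import loss_and_gradients
from .matching import MatchResult, decode_offsets, match_anchors

__all__ = ["TrainConfig", "Checkpoint", "learning_rate", "train", "predict_tile"]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.003
    decay_factor: float = 0.95
    decay_steps: int = 100
    batch_size: int = 20
    n_classes: int = 1
    l2_weight: float = 1e-4
    alpha: float = 1.0
    score_threshold: float = 0.2
    match_iou: float = 0.5
    neg_pos_ratio: int = 3
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-3
    momentum: float = 0.9
    ema_decay: float = 0.995
    max_steps: int = 800
    eval_interval: int = 100
    early_stop_patience: int = 5
    map_tie_band: float = 0.005
    input_width: int = 512
    input_height: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.initial_lr,
            self.decay_factor,
            self.decay_steps,
            self.batch_size,
            self.max_steps,
            self.eval_interval,
            self.early_stop_patience,
        ) <= 0:
            raise ValueError("all schedule parameters must be positive")
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold must lie in (0, 1)")
        if not 0.0 < self.match_iou < 1.0:
            raise ValueError("match_iou must lie in (0, 1)")


def learning_rate(config: TrainConfig, step: int) -> float:
    """Staircase schedule: initial * decay^(step // decay_steps)."""
    return config.initial_lr * config.decay_factor ** (step // config.decay_steps)


@dataclass
class Checkpoint:
    """Trained head weights plus everything needed to reproduce predictions."""

    weights: dict[str, np.ndarray]
    feat_mean: np.ndarray
    feat_std: np.ndarray
    anchor_config: AnchorConfig
    feature_config: FeatureConfig
    train_config: TrainConfig
    best_val_map: float = float("nan")
    step: int = 0
    _grids: dict = field(default_factory=dict, repr=False)

    def anchors_for(self, width: int, height: int) -> AnchorGrid:
        key = (width, height)
        if key not in self._grids:
            self._grids[key] = build_anchors((width, height), self.anchor_config)
        return self._grids[key]

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "weights.npz",
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            **self.weights,
        )
        meta = {
            "anchor_config": self.anchor_config.to_json(),
            "feature_config": self.feature_config.to_json(),
            "train_config": asdict(self.train_config),
            "best_val_map": self.best_val_map,
            "step": self.step,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        return directory

    @staticmethod
    def load(directory: str | Path) -> "Checkpoint":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        data = np.load(directory / "weights.npz")
        weights = {k: data[k] for k in ("Wc", "bc", "Wl", "bl")}
        return Checkpoint(
            weights=weights,
            feat_mean=data["feat_mean"],
            feat_std=data["feat_std"],
            anchor_config=AnchorConfig.from_json(meta["anchor_config"]),
            feature_config=FeatureConfig.from_json(meta["feature_config"]),
            train_config=TrainConfig(**meta["train_config"]),
            best_val_map=float(meta["best_val_map"]),
            step=int(meta["step"]),
        )


def _head_forward(
    feats: np.ndarray, weights: dict[str, np.ndarray], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor logits (N, 2) and offsets (N, 4) from (C, D) cell features."""
    logits = (feats @ weights["Wc"] + weights["bc"]).reshape(-1, k, 2).reshape(-1, 2)
    offsets = (feats @ weights["Wl"] + weights["bl"]).reshape(-1, k, 4).reshape(-1, 4)
    return logits, offsets


def _head_backward(
    feats: np.ndarray, grad_logits: np.ndarray, grad_offsets: np.ndarray, k: int
) -> dict[str, np.ndarray]:
    c = feats.shape[0]
    gl = grad_logits.reshape(c, k * 2)
    go = grad_offsets.reshape(c, k * 4)
    return {
        "Wc": feats.T @ gl,
        "bc": gl.sum(axis=0),
        "Wl": feats.T @ go,
        "bl": go.sum(axis=0),
    }


def _prepare_tile(
    image: np.ndarray,
    boxes: list[BoundingBox],
    feature_config: FeatureConfig,
    anchors: AnchorGrid,
    match_iou: float,
) -> tuple[np.ndarray, MatchResult]:
    f = extract_features(image, feature_config).reshape(-1, feature_config.n_features)
    return f.astype(np.float64), match_anchors(boxes, anchors, match_iou)


def _decode_predictions(
    feats_norm: np.ndarray,
    weights: dict[str, np.ndarray],
    anchors: AnchorGrid,
    score_threshold: float,
    k: int,
) -> list[Detection]:
    logits, offsets = _head_forward(feats_norm, weights, k)
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    scores = p[:, 1] / p.sum(axis=1)
    keep = np.flatnonzero(scores >= score_threshold)
    if keep.size == 0:
        return []
    corners = decode_offsets(offsets[keep], _subset(anchors, keep))
    out = []
    for (x0, y0, x1, y1), sc in zip(corners, scores[keep]):
        xi0 = int(np.clip(round(x0), 0, anchors.input_width - 1))
        yi0 = int(np.clip(round(y0), 0, anchors.input_height - 1))
        xi1 = int(np.clip(round(x1), xi0 + 1, anchors.input_width))
        yi1 = int(np.clip(round(y1), yi0 + 1, anchors.input_height))
        out.append(Detection(BoundingBox(xi0, yi0, xi1, yi1), float(sc)))
    out.sort(key=lambda d: (-d.score, d.box.x_min, d.box.y_min))
    return out


def _subset(anchors: AnchorGrid, idx: np.ndarray) -> AnchorGrid:
    return AnchorGrid(
        cx=anchors.cx[idx],
        cy=anchors.cy[idx],
        w=anchors.w[idx],
        h=anchors.h[idx],
        input_width=anchors.input_width,
        input_height=anchors.input_height,
        config=anchors.config,
    )


def predict_tile(
    checkpoint: Checkpoint,
    tile_image: np.ndarray,
    score_threshold: float = 0.2,
    nms_iou: float | None = None,
) -> list[Detection]:
    """Detections on one tile: decode anchors, drop scores below threshold, clip.

    ``nms_iou`` optionally applies decode-time suppression of duplicate anchor
    firings; the default leaves suppression to the caller (the full-image
    pipeline pools detections across tiles before its own NMS).
    """
    cfg = checkpoint.train_config
    img = np.asarray(tile_image)
    if img.shape != (cfg.input_height, cfg.input_width):
        raise ValueError(
            f"tile shape {img.shape[::-1]} != model input "
            f"{(cfg.input_width, cfg.input_height)}"
        )
    anchors = checkpoint.anchors_for(cfg.input_width, cfg.input_height)
    k = sum(checkpoint.anchor_config.anchors_per_cell)
    feats = extract_features(img, checkpoint.feature_config).reshape(-1, len(checkpoint.feat_mean))
    feats = (feats - checkpoint.feat_mean) / checkpoint.feat_std
    dets = _decode_predictions(feats, checkpoint.weights, anchors, score_threshold, k)
    if nms_iou is not None:
        from ..stitch import nms

        dets = nms(dets, nms_iou)
    return dets


def _validation_map(
    val_feats: list[np.ndarray],
    val_boxes: list[list[BoundingBox]],
    weights: dict[str, np.ndarray],
    anchors: AnchorGrid,
    k: int,
) -> float:
    from ..evaluate import mean_average_precision
    from ..stitch import nms

    per_image = []
    for feats, boxes in zip(val_feats, val_boxes):
        dets = _decode_predictions(feats, weights, anchors, 0.05, k)
        per_image.append((nms(dets, 0.45), boxes))
    ap = mean_average_precision(per_image, iou=0.5)
    return 0.0 if ap is None else ap


def train(
    train_tiles: list[tuple[np.ndarray, list[BoundingBox]]],
    val_tiles: list[tuple[np.ndarray, list[BoundingBox]]],
    config: TrainConfig = TrainConfig(),
    checkpoint_dir: str | Path | None = None,
    anchor_config: AnchorConfig = DEFAULT_ANCHOR_CONFIG,
    feature_config: FeatureConfig = FeatureConfig(),
) -> Checkpoint:
    """Train the anchor head; returns the best checkpoint by validation mAP@0.5.

    ``train_tiles``/``val_tiles`` are (grayscale image, ground-truth boxes)
    pairs at the configured input size.  Fully deterministic for a fixed
    config (all randomness flows from ``config.seed``).
    """
    if not train_tiles or not val_tiles:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    anchors = build_anchors((config.input_width, config.input_height), anchor_config)
    k = sum(anchor_config.anchors_per_cell)
    d = feature_config.n_features

    prepared = [
        _prepare_tile(img, boxes, feature_config, anchors, config.match_iou)
        for img, boxes in train_tiles
    ]
    all_feats = np.concatenate([f for f, _ in prepared], axis=0)
    feat_mean = all_feats.mean(axis=0)
    feat_std = all_feats.std(axis=0) + 1e-6
    train_feats = [(f - feat_mean) / feat_std for f, _ in prepared]
    train_matches = [m for _, m in prepared]

    val_feats = []
    val_boxes = []
    val_matches = []
    for img, boxes in val_tiles:
        f = extract_features(img, feature_config).reshape(-1, d)
        val_feats.append((f - feat_mean) / feat_std)
        val_boxes.append(boxes)
        val_matches.append(match_anchors(boxes, anchors, config.match_iou))

    weights = {
        "Wc": rng.normal(0.0, 0.01, size=(d, k * 2)),
        "bc": np.zeros(k * 2),
        "Wl": rng.normal(0.0, 0.01, size=(d, k * 4)),
        "bl": np.zeros(k * 4),
    }
    # bias the background class up so the detector starts quiet
    weights["bc"] = weights["bc"].reshape(k, 2)
    weights["bc"][:, 0] = 2.0
    weights["bc"] = weights["bc"].reshape(-1)

    rms = {name: np.zeros_like(w) for name, w in weights.items()}
    mom = {name: np.zeros_like(w) for name, w in weights.items()}
    # evaluation/checkpointing uses an exponential moving average of the
    # weights: per-parameter RMSprop steps oscillate once the loss plateaus,
    # and the EMA tracks the stable center of that oscillation
    ema = {name: w.copy() for name, w in weights.items()}

    best: Checkpoint | None = None
    best_map = -1.0
    best_val_loss = np.inf
    evals_since_improvement = 0
    log_rows = []
    order = rng.permutation(len(train_feats))
    cursor = 0

    for step in range(config.max_steps):
        lr = learning_rate(config, step)
        batch_idx = []
        for _ in range(config.batch_size):
            if cursor >= len(order):
                order = rng.permutation(len(train_feats))
                cursor = 0
            batch_idx.append(int(order[cursor]))
            cursor += 1

        grads = {name: np.zeros_like(w) for name, w in weights.items()}
        batch_loss = 0.0
        for ti in batch_idx:
            feats = train_feats[ti]
            logits, offsets = _head_forward(feats, weights, k)
            breakdown, gl, go = loss_and_gradients(
                logits, offsets, train_matches[ti], config.alpha, config.neg_pos_ratio
            )
            batch_loss += breakdown.total
            if breakdown.n_matched > 0 or gl.any():
                for name, g in _head_backward(feats, gl, go, k).items():
                    grads[name] += g
        batch_loss /= config.batch_size
        if not np.isfinite(batch_loss):
            raise RuntimeError(f"training diverged at step {step}: loss={batch_loss}")
        for name in grads:
            grads[name] /= config.batch_size
        grads["Wc"] += 2.0 * config.l2_weight * weights["Wc"]
        grads["Wl"] += 2.0 * config.l2_weight * weights["Wl"]

        for name, g in grads.items():
            rms[name] = config.rmsprop_decay * rms[name] + (1 - config.rmsprop_decay) * g * g
            mom[name] = config.momentum * mom[name] + lr * g / np.sqrt(
                rms[name] + config.rmsprop_eps
            )
            weights[name] = weights[name] - mom[name]
            if config.ema_decay > 0:
                # bias-corrected EMA so early evaluations are not dragged
                # toward the random initialization
                d = min(config.ema_decay, (step + 1.0) / (step + 10.0))
                ema[name] = d * ema[name] + (1 - d) * weights[name]

        is_eval = (step + 1) % config.eval_interval == 0 or step + 1 == config.max_steps
        val_map = float("nan")
        val_loss = float("nan")
        if is_eval:
            eval_weights = ema if config.ema_decay > 0 else weights
            val_map = _validation_map(val_feats, val_boxes, eval_weights, anchors, k)
            val_loss = 0.0
            for feats, m in zip(val_feats, val_matches):
                logits, offsets = _head_forward(feats, eval_weights, k)
                val_loss += loss_and_gradients(
                    logits, offsets, m, config.alpha, config.neg_pos_ratio
                )[0].total
            val_loss /= len(val_feats)
            # "performing better": higher validation mAP, or near-equal mAP
            # with lower validation loss.  mAP@0.5 saturates (and jitters by a
            # fraction of a percent) early on easy data while localization
            # keeps converging, so loss breaks ties within the jitter band.
            improved = val_map > best_map + 1e-9 or (
                val_map >= best_map - config.map_tie_band and val_loss < best_val_loss
            )
            if improved:
                best_map = max(val_map, best_map)
                best_val_loss = min(val_loss, best_val_loss)
                best = Checkpoint(
                    weights={name: w.copy() for name, w in eval_weights.items()},
                    feat_mean=feat_mean.copy(),
                    feat_std=feat_std.copy(),
                    anchor_config=anchor_config,
                    feature_config=feature_config,
                    train_config=config,
                    best_val_map=best_map,
                    step=step + 1,
                )
                if checkpoint_dir is not None:
                    best.save(checkpoint_dir)
                evals_since_improvement = 0
            else:
                evals_since_improvement += 1
        log_rows.append(
            {"step": step, "lr": lr, "loss": batch_loss, "val_map": val_map, "val_loss": val_loss}
        )
        if is_eval and evals_since_improvement >= config.early_stop_patience:
            break

    assert best is not None
    if checkpoint_dir is not None:
        with open(Path(checkpoint_dir) / "training_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["step", "lr", "loss", "val_map", "val_loss"]
            )
            writer.writeheader()
            writer.writerows(log_rows)
    best.training_log = log_rows  # type: ignore[attr-defined]
    return best
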