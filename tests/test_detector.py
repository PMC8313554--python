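"""Detector internals: anchors, matching, loss, schedule, training behavior."""

import math

import numpy as np
import pytest

import stomadet as sd
from stomadet.detector import (
    AnchorConfig,
    AnchorLevel,
    TrainConfig,
    build_anchors,
    compute_loss,
    learning_rate,
    match_anchors,
    predict_tile,
    smooth_l1,
    train,
)
from stomadet.detector.loss import loss_and_gradients
from stomadet.detector.matching import decode_offsets, encode_boxes, iou_matrix

SMALL_ANCHORS = AnchorConfig(levels=(AnchorLevel(stride=64, sizes=((48.0, 32.0), (64.0, 64.0))),))


class TestAnchors:
    def test_counting(self):
        cfg = AnchorConfig(levels=(AnchorLevel(stride=16, sizes=((32.0, 24.0),) * 3),))
        grid = build_anchors((512, 512), cfg)
        assert grid.n_anchors == 32 * 32 * 3

    def test_single_cell_centered(self):
        cfg = AnchorConfig(levels=(AnchorLevel(stride=128, sizes=((64.0, 64.0),)),))
        grid = build_anchors((128, 128), cfg)
        assert grid.n_anchors == 1
        assert (grid.cx[0], grid.cy[0]) == (64.0, 64.0)

    def test_determinism(self):
        a = build_anchors((256, 256), SMALL_ANCHORS)
        b = build_anchors((256, 256), SMALL_ANCHORS)
        assert np.array_equal(a.corners, b.corners)

    def test_indivisible_stride_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_anchors((250, 256), SMALL_ANCHORS)

    def test_positive_area(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        c = grid.corners
        assert ((c[:, 2] - c[:, 0]) > 0).all() and ((c[:, 3] - c[:, 1]) > 0).all()


class TestMatching:
    def test_identity_match_zero_offsets(self):
        grid = build_anchors((128, 128), AnchorConfig(
            levels=(AnchorLevel(stride=128, sizes=((64.0, 64.0),)),)
        ))
        gt = np.array([[32.0, 32.0, 96.0, 96.0]])  # exactly the single anchor
        m = match_anchors(gt, grid, 0.5)
        assert m.n_matched == 1
        assert np.allclose(m.targets[0], 0.0)

    def test_no_gt_all_negative(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        m = match_anchors([], grid, 0.5)
        assert m.n_matched == 0 and (m.labels == 0).all()

    def test_every_gt_gets_a_positive_anchor(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rng.integers(0, 200, size=(4, 2))
            gt = np.hstack([g, g + rng.integers(8, 56, size=(4, 2))]).astype(float)
            m = match_anchors(gt, grid, 0.5)
            assert set(range(len(gt))) <= set(m.gt_index[m.gt_index >= 0].tolist())

    def test_matches_brute_force_oracle(self):
        """Positives equal an exhaustive loop: IoU >= threshold plus unique forced bests."""
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        corners = grid.corners
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(1, 6))
            g = rng.integers(0, 180, size=(k, 2))
            gt = np.hstack([g, g + rng.integers(16, 70, size=(k, 2))]).astype(float)
            ious = [
                [float(iou_matrix(gt[gi], corners[a])[0, 0]) for a in range(len(corners))]
                for gi in range(k)
            ]
            expected = {a for gi in range(k) for a, v in enumerate(ious[gi]) if v >= 0.5}
            # each gt claims its best unclaimed anchor, best-matched gts first
            claimed = set()
            for gi in sorted(range(k), key=lambda i: -max(ious[i])):
                for a in sorted(range(len(corners)), key=lambda a: -ious[gi][a]):
                    if a not in claimed:
                        claimed.add(a)
                        break
            expected |= claimed
            m = match_anchors(gt, grid, 0.5)
            assert set(np.flatnonzero(m.labels == 1).tolist()) == expected

    def test_encode_decode_round_trip(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        gt = np.array([[40.0, 40.0, 90.0, 80.0]])
        idx = np.array([5])
        off = encode_boxes(gt, grid, idx)
        full = np.zeros((grid.n_anchors, 4))
        full[5] = off
        assert np.allclose(decode_offsets(full, grid)[5], gt[0])


class TestLoss:
    def one_anchor_grid(self):
        return build_anchors((128, 128), AnchorConfig(
            levels=(AnchorLevel(stride=128, sizes=((64.0, 64.0),)),)
        ))

    def test_smooth_l1_closed_form(self):
        assert smooth_l1(0.5) == pytest.approx(0.125)
        assert smooth_l1(2.0) == pytest.approx(1.5)
        assert smooth_l1(-1.0) == pytest.approx(0.5)

    def test_single_anchor_hand_computation(self):
        grid = self.one_anchor_grid()
        m = match_anchors(np.array([[32.0, 32.0, 96.0, 96.0]]), grid, 0.5)
        logits = np.array([[0.0, 0.0]])
        offsets = np.full((1, 4), 0.5)
        br = compute_loss(logits, offsets, m, alpha=1.0)
        # L_c = softmax CE at even logits = ln 2; L_l = 4 * smoothL1(0.5)
        assert br.classification == pytest.approx(math.log(2))
        assert br.localization == pytest.approx(0.5)
        assert br.total == pytest.approx(math.log(2) + 0.5)

    def test_perfect_predictions_limit(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        gt = np.array([[32.0, 32.0, 96.0, 96.0], [128.0, 128.0, 192.0, 160.0]])
        m = match_anchors(gt, grid, 0.5)
        logits = np.tile([20.0, -20.0], (grid.n_anchors, 1))
        logits[m.labels == 1] = [-20.0, 20.0]
        br = compute_loss(logits, m.targets.copy(), m)
        assert br.localization == 0.0
        assert br.total < 1e-10

    def test_zero_matches_zero_loss(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        m = match_anchors([], grid, 0.5)
        br = compute_loss(np.zeros((grid.n_anchors, 2)), np.zeros((grid.n_anchors, 4)), m)
        assert br.total == 0.0 and br.n_matched == 0

    def test_hard_negative_ratio(self):
        grid = build_anchors((256, 256), SMALL_ANCHORS)
        gt = np.array([[32.0, 32.0, 96.0, 96.0]])
        m = match_anchors(gt, grid, 0.5)
        logits = np.zeros((grid.n_anchors, 2))
        _, grad_logits, _ = loss_and_gradients(logits, np.zeros((grid.n_anchors, 4)), m, neg_pos_ratio=3)
        touched = np.flatnonzero(np.abs(grad_logits).sum(axis=1) > 0)
        assert touched.size == m.n_matched + 3 * m.n_matched

    def test_gradient_matches_finite_difference(self):
        grid = self.one_anchor_grid()
        m = match_anchors(np.array([[30.0, 30.0, 90.0, 100.0]]), grid, 0.5)
        logits = np.array([[0.3, -0.2]])
        offsets = np.array([[0.4, -0.6, 0.2, 1.7]])
        _, gl, go = loss_and_gradients(logits, offsets, m)
        eps = 1e-6
        for arr, grad in ((logits, gl), (offsets, go)):
            for j in range(arr.shape[1]):
                arr_p = arr.copy()
                arr_p[0, j] += eps
                a = compute_loss(arr_p if arr is logits else logits,
                                 arr_p if arr is offsets else offsets, m).total
                arr_m = arr.copy()
                arr_m[0, j] -= eps
                b = compute_loss(arr_m if arr is logits else logits,
                                 arr_m if arr is offsets else offsets, m).total
                assert grad[0, j] == pytest.approx((a - b) / (2 * eps), abs=1e-5)


class TestSchedule:
    def test_closed_form(self):
        cfg = TrainConfig()
        assert learning_rate(cfg, 0) == pytest.approx(0.003)
        assert learning_rate(cfg, 99) == pytest.approx(0.003)
        assert learning_rate(cfg, 100) == pytest.approx(0.00285)
        for step in (0, 57, 100, 250, 999):
            assert learning_rate(cfg, step) == pytest.approx(0.003 * 0.95 ** (step // 100))


def small_training_tiles(n_images=3):
    cfg = sd.GeneratorConfig(
        image_width_px=512, image_height_px=256, physical_width_um=450,
        physical_height_um=225, count_mean=10, count_sd=2, size_mean_um=34,
        size_sd_um=2.7, defocus_prob=0.0, brightness_shift_prob=0.0,
    )
    tiles = []
    for s in range(n_images):
        mg, gt = sd.generate_micrograph(cfg, 100 + s)
        for spec in sd.split_fixed(mg, 256, 128):
            tiles.append((spec.crop(mg.pixels), sd.tile_annotations(gt.boxes, spec)))
    return tiles


class TestTraining:
    def test_training_determinism(self):
        tiles = small_training_tiles()
        cfg = TrainConfig(
            max_steps=40, eval_interval=20, batch_size=4,
            input_width=256, input_height=128, seed=5,
        )
        c1 = train(tiles[:6], tiles[6:8], cfg)
        c2 = train(tiles[:6], tiles[6:8], cfg)
        assert c1.best_val_map == c2.best_val_map
        for k in c1.weights:
            assert np.array_equal(c1.weights[k], c2.weights[k])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], [], TrainConfig())

    def test_smoke_training_reaches_high_map(self, trained_checkpoint):
        assert trained_checkpoint.best_val_map >= 0.9

    def test_checkpoint_save_load_round_trip(self, trained_checkpoint, tmp_path):
        from stomadet.detector import Checkpoint

        trained_checkpoint.save(tmp_path / "ckpt")
        loaded = Checkpoint.load(tmp_path / "ckpt")
        tile = np.full((512, 512), 180, dtype=np.uint8)
        a = predict_tile(trained_checkpoint, tile, 0.2)
        b = predict_tile(loaded, tile, 0.2)
        assert [(d.box, d.score) for d in a] == [(d.box, d.score) for d in b]


class TestPredictTile:
    def test_blank_tile_no_detections(self, trained_checkpoint, blank_micrograph):
        tile = blank_micrograph.pixels[:512, :512]
        assert predict_tile(trained_checkpoint, tile, 0.2) == []

    def test_threshold_one_empty(self, trained_checkpoint):
        mg, _ = sd.generate_micrograph(sd.preset("A"), 31415)
        tile = mg.pixels[:512, :512]
        assert predict_tile(trained_checkpoint, tile, 1.0) == []

    def test_threshold_monotonicity(self, trained_checkpoint):
        mg, _ = sd.generate_micrograph(sd.preset("A"), 31415)
        tile = mg.pixels[:512, :512]
        n = [len(predict_tile(trained_checkpoint, tile, t)) for t in (0.8, 0.5, 0.2, 0.05)]
        assert n == sorted(n)

    def test_wrong_input_size_rejected(self, trained_checkpoint):
        with pytest.raises(ValueError, match="input"):
            predict_tile(trained_checkpoint, np.zeros((128, 128), dtype=np.uint8))

    def test_determinism(self, trained_checkpoint):
        mg, _ = sd.generate_micrograph(sd.preset("C"), 2718)
        tile = mg.pixels[:512, :512]
        a = predict_tile(trained_checkpoint, tile, 0.2)
        b = predict_tile(trained_checkpoint, tile, 0.2)
        assert [(d.box, d.score) for d in a] == [(d.box, d.score) for d in b]
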