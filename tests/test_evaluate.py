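"""Detection scoring: greedy matching, precision/recall aggregation, AP."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from stomadet.evaluate import match_detections, mean_average_precision, precision_recall
from stomadet.io import BoundingBox, Detection
from stomadet.stitch import iou


def det(x0, y0, x1, y1, score):
    return Detection(BoundingBox(x0, y0, x1, y1), score)


class TestMatchDetections:
    def test_exact_hit(self):
        tp, matched = match_detections([det(0, 0, 10, 10, 0.9)], [BoundingBox(0, 0, 10, 10)])
        assert tp == [True] and matched == [True]

    def test_duplicate_is_false_positive(self):
        dets = [det(0, 0, 10, 10, 0.9), det(1, 1, 11, 11, 0.8)]
        tp, matched = match_detections(dets, [BoundingBox(0, 0, 10, 10)])
        assert tp == [True, False] and matched == [True]

    def test_iou50_rejects_weak_overlap(self):
        dets = [det(0, 0, 10, 10, 0.9)]
        gt = [BoundingBox(8, 8, 18, 18)]  # IoU = 4/196
        assert match_detections(dets, gt, "overlap")[0] == [True]
        assert match_detections(dets, gt, "iou50")[0] == [False]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], "coco")

    def test_greedy_close_to_optimal_assignment(self):
        """Greedy score-ordered matching vs maximum bipartite matching (iou50)."""
        rng = np.random.default_rng(5)
        shortfall = 0
        total_gt = 0
        for _ in range(100)            :
            n_det, n_gt = rng.integers(1, 9, 2)
            gts = []
            for _ in range(n_gt):
                x0, y0 = rng.integers(0, 60, 2)
                gts.append(BoundingBox(int(x0), int(y0), int(x0 + rng.integers(8, 20)),
                                       int(y0 + rng.integers(8, 20))))
            dets = []
            for _ in range(n_det):
                base = gts[int(rng.integers(0, n_gt))]
                dx, dy = rng.integers(-4, 5, 2)
                dets.append(det(base.x_min + int(dx), base.y_min + int(dy),
                                base.x_max + int(dx), base.y_max + int(dy),
                                float(rng.uniform(0.1, 1.0))))
            tp_flags, _ = match_detections(dets, gts, "iou50")
            adj = np.zeros((len(dets), len(gts)), dtype=int)
            for i, d in enumerate(dets):
                for j, g in enumerate(gts):
                    adj[i, j] = int(iou(d.box, g) >= 0.5)
            opt = int((maximum_bipartite_matching(csr_matrix(adj), perm_type="column") >= 0).sum())
            assert sum(tp_flags) <= opt
            shortfall += opt - sum(tp_flags)
            total_gt += n_gt
        # greedy one-to-one matching may fall short of optimal only on rare ties
        assert shortfall <= 0.02 * total_gt


class TestPrecisionRecall:
    def test_perfect_detection(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(30, 30, 40, 40)]
        dets = [det(0, 0, 10, 10, 0.9), det(30, 30, 40, 40, 0.8)]
        res = precision_recall([(dets, gt)])
        assert res.precision_mean == 1.0 and res.recall_mean == 1.0

    def test_ratio_arithmetic(self):
        gt = [BoundingBox(12 * i, 0, 12 * i + 10, 10) for i in range(99)]
        dets = [det(12 * i, 0, 12 * i + 10, 10, 0.9) for i in range(99)]
        dets.append(det(0, 500, 10, 510, 0.5))  # one stray false positive
        res = precision_recall([(dets, gt)])
        assert res.precision_mean == pytest.approx(0.99)
        assert res.recall_mean == pytest.approx(1.0)

    def test_set_mean_over_images(self):
        g = [BoundingBox(0, 0, 10, 10)]
        hit = [det(0, 0, 10, 10, 0.9)]
        miss = []
        res = precision_recall([(hit, g), (miss, g), (hit, g)])
        assert res.recall_mean == pytest.approx((1 + 0 + 1) / 3)
        assert res.precision_mean == pytest.approx(1.0)  # empty image: precision 1.0

    def test_empty_image_convention(self):
        res = precision_recall([([], [])])
        assert res.precision_mean == 1.0 and res.recall_mean == 1.0

    def test_count_identities(self):
        rng = np.random.default_rng(2)
        gts = [BoundingBox(int(x), int(y), int(x) + 10, int(y) + 10)
               for x, y in rng.integers(0, 200, (10, 2))]
        dets = [det(b.x_min + 2, b.y_min, b.x_max + 2, b.y_max, float(rng.uniform(0.2, 1)))
                for b in gts[:6]]
        res = precision_recall([(dets, gts)], mode="iou50")
        assert res.true_positives + res.false_negatives == len(gts)
        assert res.true_positives + res.false_positives == len(dets)

    def test_overlap_mode_at_least_as_generous_as_iou50(self):
        rng = np.random.default_rng(3)
        gts = [BoundingBox(int(x), int(y), int(x) + 12, int(y) + 12)
               for x, y in rng.integers(0, 150, (8, 2))]
        dets = [det(b.x_min + int(rng.integers(0, 9)), b.y_min, b.x_max + int(rng.integers(0, 9)),
                    b.y_max, float(rng.uniform(0.2, 1))) for b in gts]
        loose = precision_recall([(dets, gts)], mode="overlap")
        strict = precision_recall([(dets, gts)], mode="iou50")
        assert loose.precision_mean >= strict.precision_mean
        assert loose.recall_mean >= strict.recall_mean


class TestMeanAveragePrecision:
    def test_perfect_detector(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(30, 30, 44, 44)]
        dets = [det(0, 0, 10, 10, 0.9), det(30, 30, 44, 44, 0.8)]
        assert mean_average_precision([(dets, gt)]) == pytest.approx(1.0)

    def test_single_wrong_detection(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        dets = [det(50, 50, 60, 60, 0.9)]
        assert mean_average_precision([(dets, gt)]) == pytest.approx(0.0)

    def test_toy_staircase_hand_computed(self):
        # 3 gts; 5 detections ranked TP, FP, TP, FP, TP
        # precision envelope integration: (1 + 2/3 + 3/5) / 3 = 34/45
        gts = [BoundingBox(0, 0, 10, 10), BoundingBox(20, 0, 30, 10), BoundingBox(40, 0, 50, 10)]
        dets = [
            det(0, 0, 10, 10, 0.95),
            det(60, 60, 70, 70, 0.9),
            det(20, 0, 30, 10, 0.85),
            det(80, 80, 90, 90, 0.8),
            det(40, 0, 50, 10, 0.75),
        ]
        assert mean_average_precision([(dets, gts)]) == pytest.approx(34 / 45)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(9)
        gts = [BoundingBox(int(x), int(y), int(x) + 10, int(y) + 10)
               for x, y in rng.integers(0, 300, (12, 2))]
        dets = []
        for b in gts[:9]:
            dx = int(rng.integers(0, 6))
            dets.append(det(b.x_min + dx, b.y_min, b.x_max + dx, b.y_max, float(rng.uniform(0.2, 0.99))))
        dets.append(det(200, 200, 210, 210, 0.5))
        ap1 = mean_average_precision([(dets, gts)])
        squared = [Detection(d.box, d.score**2) for d in dets]
        ap2 = mean_average_precision([(squared, gts)])
        assert ap1 == pytest.approx(ap2)

    def test_no_ground_truth_undefined(self):
        assert mean_average_precision([([], [])]) is None
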