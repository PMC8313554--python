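"""Shared test helpers: independent oracle implementations."""

from stomadet.io import BoundingBox, Detection
from stomadet.stitch import iou


def brute_force_nms(dets, thr):
    """Independent NMS formulation: keep a box iff IoU <= thr against every kept box."""
    ordered = sorted(dets, key=lambda d: (-d.score, d.box.x_min, d.box.y_min))
    kept = []
    for d in ordered:
        if all(iou(d.box, k.box) <= thr for k in kept):
            kept.append(d)
    return kept


def random_detections(rng, n, extent=100):
    out = []
    for _ in range(n):
        x0, y0 = rng.integers(0, extent - 20, 2)
        w, h = rng.integers(5, 25, 2)
        out.append(
            Detection(
                BoundingBox(int(x0), int(y0), int(x0 + w), int(y0 + h)),
                float(rng.uniform(0.05, 1.0)),
            )
        )
    return out
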