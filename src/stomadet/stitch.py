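"""Full-micrograph inference: overlapping tiles, global remapping, cross-tile NMS.

A stoma lying in an overlap zone is predicted by more than one tile; greedy
non-maximum suppression over the pooled, globally-remapped detections keeps
one box per stoma.  The suppression threshold follows the pipeline default of
0.01 -- effectively "keep at most one box per physical stoma" -- and uses a
strict ``>`` comparison, so a threshold of 0 would still allow touching boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import BoundingBox, Detection, Micrograph
from .tiling import box_to_global, split_overlapping

__all__ = ["ImageDetections", "iou", "nms", "nms_with_voting", "detect_full_image"]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes; symmetric, in [0, 1]."""
    ix0 = max(a.x_min, b.x_min)
    iy0 = max(a.y_min, b.y_min)
    ix1 = min(a.x_max, b.x_max)
    iy1 = min(a.y_max, b.y_max)
    inter = max(ix1 - ix0, 0) * max(iy1 - iy0, 0)
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression, strict ``>`` comparison.

    Detections are processed in descending score order (ties broken by box
    position for determinism); each kept detection suppresses all remaining
    ones whose IoU with it exceeds the threshold.  Output is sorted by
    descending score.
    """
    if not 0.0 <= iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in [0, 1)")
    pending = sorted(detections, key=lambda d: (-d.score, d.box.x_min, d.box.y_min))
    kept: list[Detection] = []
    while pending:
        top = pending.pop(0)
        kept.append(top)
        pending = [d for d in pending if iou(top.box, d.box) <= iou_threshold]
    return kept


def nms_with_voting(
    detections: list[Detection],
    iou_threshold: float,
    vote_iou: float = 0.4,
    image_width: int | None = None,
    image_height: int | None = None,
) -> list[Detection]:
    """Greedy NMS with box voting: each survivor's coordinates become the
    score-weighted mean over its well-overlapping candidates (IoU > vote_iou).

    Averaging the duplicate predictions of one stoma -- from neighboring
    anchors and from overlapping tiles -- can damp per-candidate localization
    noise when the regression head is noisy; with a well-converged head the
    plain top box is already unbiased, so voting is optional.  Survivors and
    scores are exactly those of :func:`nms`; only kept coordinates change.
    """
    if not 0.0 <= iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in [0, 1)")
    pending = sorted(detections, key=lambda d: (-d.score, d.box.x_min, d.box.y_min))
    kept: list[Detection] = []
    while pending:
        top = pending.pop(0)
        voters = [top] + [d for d in pending if iou(top.box, d.box) > vote_iou]
        w = sum(d.score for d in voters)
        x0, y0, x1, y1 = (
            int(round(sum(d.score * d.box.as_tuple()[i] for d in voters) / w))
            for i in range(4)
        )
        if image_width is not None:
            x0, x1 = max(x0, 0), min(x1, image_width)
        if image_height is not None:
            y0, y1 = max(y0, 0), min(y1, image_height)
        if x1 <= x0 or y1 <= y0:  # degenerate after rounding; keep the original
            kept.append(top)
        else:
            kept.append(Detection(BoundingBox(x0, y0, x1, y1), top.score))
        pending = [d for d in pending if iou(top.box, d.box) <= iou_threshold]
    return kept


@dataclass
class ImageDetections:
    source_id: str
    detections: list[Detection]
    tile_w: int = 0
    tile_h: int = 0
    overlap_x: int = 0
    overlap_y: int = 0
    score_threshold: float = 0.2
    nms_iou: float = 0.01
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def boxes(self) -> list[BoundingBox]:
        return [d.box for d in self.detections]


def detect_full_image(
    checkpoint,
    micrograph: Micrograph,
    tile_w: int = 512,
    tile_h: int = 512,
    overlap_x: int = 120,
    overlap_y: int = 40,
    score_threshold: float = 0.2,
    nms_iou: float = 0.01,
    edge_trim_px: int = 0,
    box_vote_iou: float | None = None,
) -> ImageDetections:
    """Detect stomata on a whole micrograph.

    Pipeline: overlapping split -> per-tile prediction -> remap to global
    coordinates -> pooled greedy NMS.  ``box_vote_iou`` optionally replaces
    each kept box's coordinates with the score-weighted mean over its
    suppression cluster (see :func:`nms_with_voting`).  ``edge_trim_px``
    optionally drops detections whose center lies within that many pixels of
    a tile border before NMS (an edge-miss mitigation, off by default).
    """
    from .detector.model import predict_tile

    tiles = split_overlapping(micrograph, tile_w, tile_h, overlap_x, overlap_y)
    pooled: list[Detection] = []
    for tile in tiles:
        for det in predict_tile(checkpoint, tile.crop(micrograph.pixels), score_threshold):
            if edge_trim_px > 0:
                cx = (det.box.x_min + det.box.x_max) / 2
                cy = (det.box.y_min + det.box.y_max) / 2
                near_left = cx < edge_trim_px and tile.x0 > 0
                near_right = cx > tile.width - edge_trim_px and tile.x0 + tile.width < micrograph.width
                near_top = cy < edge_trim_px and tile.y0 > 0
                near_bottom = (
                    cy > tile.height - edge_trim_px
                    and tile.y0 + tile.height < micrograph.height
                )
                if near_left or near_right or near_top or near_bottom:
                    continue
            gbox = box_to_global(det.box, tile, micrograph.width, micrograph.height)
            pooled.append(Detection(gbox, det.score))
    if box_vote_iou is None:
        final = nms(pooled, nms_iou)
    else:
        final = nms_with_voting(
            pooled, nms_iou, box_vote_iou, micrograph.width, micrograph.height
        )
    return ImageDetections(
        source_id=micrograph.source_id,
        detections=final,
        tile_w=tile_w,
        tile_h=tile_h,
        overlap_x=overlap_x,
        overlap_y=overlap_y,
        score_threshold=score_threshold,
        nms_iou=nms_iou,
        extra={"n_tiles": len(tiles), "n_raw_detections": len(pooled)},
    )
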