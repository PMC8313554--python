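"""Photometric training-set augmentation: blur and brightness variants.

All four transforms are photometric only, so bounding boxes pass through
unchanged.  Brighten multiplies intensities (saturating at 255); darken uses
integer floor division so a factor-2 darkening maps 120 -> 60 exactly.  Blur
parameters default to a visibly defocused but still detectable appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_bilateral

from .io import BoundingBox

__all__ = ["AugmentationSpec", "DEFAULT_SPECS", "augment_tile", "augment_dataset"]

KINDS = ("bilateral_blur", "gaussian_blur", "brighten", "darken")


@dataclass(frozen=True)
class AugmentationSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}; valid: {KINDS}")
        factor = self.params.get("factor")
        if self.kind in ("brighten", "darken") and factor is not None and factor <= 0:
            raise ValueError("brighten/darken factor must be > 0")


#: brightened and darkened by a factor of 2 plus both blur flavours
DEFAULT_SPECS = (
    AugmentationSpec("gaussian_blur", {"sigma": 2.0}),
    AugmentationSpec("bilateral_blur", {"win_size": 9, "sigma_color": 0.15, "sigma_spatial": 3.0}),
    AugmentationSpec("brighten", {"factor": 2.0}),
    AugmentationSpec("darken", {"factor": 2.0}),
)


def augment_tile(
    tile_image: np.ndarray, boxes: list[BoundingBox], spec: AugmentationSpec
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Apply one photometric transform; annotations are returned unchanged."""
    img = np.asarray(tile_image, dtype=np.uint8)
    p = spec.params
    if spec.kind == "gaussian_blur":
        out = ndimage.gaussian_filter(img.astype(float), sigma=p.get("sigma", 2.0))
        out = np.clip(out, 0, 255).round().astype(np.uint8)
    elif spec.kind == "bilateral_blur":
        f = denoise_bilateral(
            img.astype(float) / 255.0,
            win_size=int(p.get("win_size", 9)),
            sigma_color=p.get("sigma_color", 0.15),
            sigma_spatial=p.get("sigma_spatial", 3.0),
        )
        out = np.clip(f * 255.0, 0, 255).round().astype(np.uint8)
    elif spec.kind == "brighten":
        factor = p.get("factor", 2.0)
        out = np.clip(img.astype(np.float64) * factor, 0, 255).astype(np.uint8)
    elif spec.kind == "darken":
        factor = p.get("factor", 2.0)
        if float(factor).is_integer():
            out = img // int(factor)  # exact floor-division semantics
        else:
            out = (img.astype(np.float64) / factor).astype(np.uint8)
    else:  # pragma: no cover - guarded by AugmentationSpec
        raise ValueError(spec.kind)
    return out, list(boxes)


def augment_dataset(
    tiles: list[tuple[np.ndarray, list[BoundingBox]]],
    selection_fraction: float,
    specs: tuple[AugmentationSpec, ...] = DEFAULT_SPECS,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, list[BoundingBox], str]], dict]:
    """Expand a tile set with augmented variants of a seeded random subset.

    Returns the expanded dataset as (image, boxes, variant_tag) triples --
    originals first, tagged "orig" -- and a bookkeeping dict with object
    counts before/after.
    """
    if not tiles:
        raise ValueError("empty tile list")
    if not 0.0 < selection_fraction <= 1.0:
        raise ValueError("selection_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sel = int(round(selection_fraction * len(tiles)))
    selected = sorted(rng.choice(len(tiles), size=n_sel, replace=False).tolist())

    out: list[tuple[np.ndarray, list[BoundingBox], str]] = [
        (img, list(boxes), "orig") for img, boxes in tiles
    ]
    objects_before = sum(len(b) for _, b in tiles)
    added_objects = 0
    for idx in selected:
        img, boxes = tiles[idx]
        for spec in specs:
            aug_img, aug_boxes = augment_tile(img, boxes, spec)
            out.append((aug_img, aug_boxes, spec.kind))
            added_objects += len(aug_boxes)
    report = {
        "tiles_before": len(tiles),
        "tiles_after": len(out),
        "selected_tiles": n_sel,
        "objects_before": objects_before,
        "objects_after": objects_before + added_objects,
    }
    return out, report
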