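"""Tiling of micrographs for training (disjoint grid) and inference (overlapping grid).

Training tiles form the maximal non-overlapping grid anchored at the origin
(a 2048x1536 micrograph yields 4x3 = 12 tiles of 512x512; remainder pixels at
the right/bottom edges are discarded).  Inference tiles overlap so that every
stoma is fully visible in at least one tile; origins advance by
``tile - overlap`` and the last tile on each axis is clamped to end exactly at
the image edge, which on 2048x1536 with 120/40 px overlap gives 5x4 = 20 tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import BoundingBox, Micrograph

__all__ = ["TileSpec", "split_fixed", "split_overlapping", "tile_annotations", "box_to_global"]


@dataclass(frozen=True)
class TileSpec:
    x0: int
    y0: int
    width: int
    height: int
    row_index: int
    col_index: int

    def crop(self, pixels):
        return pixels[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]

    @property
    def box(self) -> BoundingBox:
        return BoundingBox(self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)


def _image_dims(micrograph) -> tuple[int, int]:
    if isinstance(micrograph, Micrograph):
        return micrograph.width, micrograph.height
    w, h = micrograph  # (width, height) pair
    return int(w), int(h)


def split_fixed(micrograph, tile_w: int, tile_h: int) -> list[TileSpec]:
    """Maximal disjoint grid of tile_w x tile_h tiles anchored at (0, 0)."""
    w, h = _image_dims(micrograph)
    if tile_w > w or tile_h > h:
        raise ValueError(f"tile {tile_w}x{tile_h} larger than image {w}x{h}")
    if tile_w <= 0 or tile_h <= 0:
        raise ValueError("tile dimensions must be positive")
    return [
        TileSpec(c * tile_w, r * tile_h, tile_w, tile_h, r, c)
        for r in range(h // tile_h)
        for c in range(w // tile_w)
    ]


def _axis_origins(extent: int, tile: int, overlap: int) -> list[int]:
    stride = tile - overlap
    n = 1 + max(0, -(-(extent - tile) // stride))  # ceil division
    origins = []
    for i in range(n):
        o = min(i * stride, extent - tile)  # clamp: tile ends at the image edge
        if not origins or o != origins[-1]:
            origins.append(o)
    return origins


def split_overlapping(
    micrograph, tile_w: int, tile_h: int, overlap_x: int, overlap_y: int
) -> list[TileSpec]:
    """Overlapping grid covering every pixel; clamped (deduplicated) at the edges."""
    w, h = _image_dims(micrograph)
    if tile_w > w or tile_h > h:
        raise ValueError(f"tile {tile_w}x{tile_h} larger than image {w}x{h}")
    if not (0 <= overlap_x < tile_w and 0 <= overlap_y < tile_h):
        raise ValueError("overlap must satisfy 0 <= overlap < tile dimension")
    xs = _axis_origins(w, tile_w, overlap_x)
    ys = _axis_origins(h, tile_h, overlap_y)
    return [
        TileSpec(x, y, tile_w, tile_h, r, c)
        for r, y in enumerate(ys)
        for c, x in enumerate(xs)
    ]


def tile_annotations(
    global_boxes: list[BoundingBox], tile: TileSpec, min_fraction: float = 0.5
) -> list[BoundingBox]:
    """Project global boxes into tile-local coordinates.

    A box is kept when at least ``min_fraction`` of its area lies inside the
    tile; kept boxes are clipped to the tile then shifted to local coordinates.
    The default 0.5 keeps majority-visible stomata and drops slivers, which
    would only be label noise for the detector.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    tx1, ty1 = tile.x0 + tile.width, tile.y0 + tile.height
    out = []
    for b in global_boxes:
        ix0, iy0 = max(b.x_min, tile.x0), max(b.y_min, tile.y0)
        ix1, iy1 = min(b.x_max, tx1), min(b.y_max, ty1)
        if ix1 <= ix0 or iy1 <= iy0:
            continue
        if (ix1 - ix0) * (iy1 - iy0) / b.area < min_fraction:
            continue
        out.append(BoundingBox(ix0 - tile.x0, iy0 - tile.y0, ix1 - tile.x0, iy1 - tile.y0))
    return out


def box_to_global(
    box: BoundingBox, tile: TileSpec, image_width: int | None = None, image_height: int | None = None
) -> BoundingBox:
    """Shift a tile-local box back to global coordinates (inverse of projection)."""
    if box.x_max > tile.width or box.y_max > tile.height or box.x_min < 0 or box.y_min < 0:
        raise ValueError(f"box {box.as_tuple()} outside tile extent {tile.width}x{tile.height}")
    g = box.shift(tile.x0, tile.y0)
    if image_width is not None and (g.x_max > image_width or g.y_max > (image_height or 0)):
        raise ValueError(f"box {g.as_tuple()} outside image bounds")
    return g
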