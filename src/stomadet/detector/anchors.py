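"""Default-box (anchor) grids.

Anchors are laid out deterministically from the configuration: for each
feature level with cell stride ``s``, one anchor of every configured
(width, height) is centered on each cell center ``((j + 0.5) s, (i + 0.5) s)``.
Anchor ordering is cell-major (row, then column), then anchor shape within the
cell -- the same ordering the detector head uses for its outputs.

Default shapes bracket oil-palm stomata at the 10x calibration used here
(about 0.88 um/px): horizontal lengths of 31.8-43.0 um correspond to box
widths of roughly 36-49 px with height/width around 1/1.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnchorLevel", "AnchorConfig", "AnchorGrid", "build_anchors", "DEFAULT_ANCHOR_CONFIG"]


@dataclass(frozen=True)
class AnchorLevel:
    stride: int
    sizes: tuple[tuple[float, float], ...]  # (width, height) pairs in px

    def __post_init__(self) -> None:
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        if not self.sizes or any(w <= 0 or h <= 0 for w, h in self.sizes):
            raise ValueError("every anchor must have positive width and height")


@dataclass(frozen=True)
class AnchorConfig:
    levels: tuple[AnchorLevel, ...]

    @property
    def anchors_per_cell(self) -> list[int]:
        return [len(lv.sizes) for lv in self.levels]

    def to_json(self) -> list:
        return [[lv.stride, [list(s) for s in lv.sizes]] for lv in self.levels]

    @staticmethod
    def from_json(data: list) -> "AnchorConfig":
        return AnchorConfig(
            tuple(
                AnchorLevel(int(stride), tuple((float(w), float(h)) for w, h in sizes))
                for stride, sizes in data
            )
        )


DEFAULT_ANCHOR_CONFIG = AnchorConfig(
    levels=(AnchorLevel(stride=8, sizes=((36.0, 26.0), (42.0, 30.0), (50.0, 36.0))),)
)


@dataclass
class AnchorGrid:
    """Flat arrays of anchor centers/sizes plus the grid bookkeeping."""

    cx: np.ndarray
    cy: np.ndarray
    w: np.ndarray
    h: np.ndarray
    input_width: int
    input_height: int
    config: AnchorConfig = field(repr=False, default=None)

    @property
    def n_anchors(self) -> int:
        return int(self.cx.size)

    @property
    def corners(self) -> np.ndarray:
        """(N, 4) array of (x_min, y_min, x_max, y_max), float."""
        return np.stack(
            [
                self.cx - self.w / 2,
                self.cy - self.h / 2,
                self.cx + self.w / 2,
                self.cy + self.h / 2,
            ],
            axis=1,
        )


def build_anchors(
    input_size: tuple[int, int], config: AnchorConfig = DEFAULT_ANCHOR_CONFIG
) -> AnchorGrid:
    """Deterministic anchor grid for a (width, height) input.

    The input must be divisible by every level's stride so cells tile exactly.
    """
    width, height = int(input_size[0]), int(input_size[1])
    cxs, cys, ws, hs = [], [], [], []
    for level in config.levels:
        s = level.stride
        if width % s or height % s:
            raise ValueError(f"input {width}x{height} not divisible by stride {s}")
        gx, gy = width // s, height // s
        ccx = (np.arange(gx) + 0.5) * s
        ccy = (np.arange(gy) + 0.5) * s
        # cell-major (row, col), then anchor shape
        grid_cy, grid_cx = np.meshgrid(ccy, ccx, indexing="ij")
        for_cell_cx = np.repeat(grid_cx.ravel(), len(level.sizes))
        for_cell_cy = np.repeat(grid_cy.ravel(), len(level.sizes))
        size_w = np.tile(np.array([s_[0] for s_ in level.sizes]), gx * gy)
        size_h = np.tile(np.array([s_[1] for s_ in level.sizes]), gx * gy)
        cxs.append(for_cell_cx)
        cys.append(for_cell_cy)
        ws.append(size_w)
        hs.append(size_h)
    return AnchorGrid(
        cx=np.concatenate(cxs),
        cy=np.concatenate(cys),
        w=np.concatenate(ws),
        h=np.concatenate(hs),
        input_width=width,
        input_height=height,
        config=config,
    )
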