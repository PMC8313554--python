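"""Micrograph and annotation I/O.

One internal coordinate convention is used everywhere: pixel coordinates are
0-based and boxes are half-open, ``[x_min, x_max) x [y_min, y_max)``, so a
box's width is exactly ``x_max - x_min``.  Pascal VOC XML files (as written by
labelImg) use 1-based *inclusive* coordinates; the conversion is an exact
integer map applied only at the file boundary:

    internal (x0, y0, x1, y1)  <->  VOC (x0 + 1, y0 + 1, x1, y1)
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "BoundingBox",
    "Detection",
    "Micrograph",
    "read_image",
    "write_image",
    "read_voc",
    "write_voc",
    "read_detections_csv",
    "write_detections_csv",
]

#: luma weights used to collapse RGB inputs to grayscale (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])

DETECTIONS_COLUMNS = ["source_id", "x_min", "y_min", "x_max", "y_max", "score"]


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box: {self!r}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def shift(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class Detection:
    """A bounding box with a confidence score in [0, 1]."""

    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0, 1]: {self.score}")


@dataclass
class Micrograph:
    """Grayscale raster with physical calibration.

    ``pitch_x_um``/``pitch_y_um`` are micrometres per pixel along each axis;
    they differ in general (e.g. 1800/2048 != 1400/1536) and are never averaged.
    """

    pixels: np.ndarray  # (H, W) uint8
    pitch_x_um: float
    pitch_y_um: float
    source_id: str = "micrograph"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D raster with positive dims")
        if not (self.pitch_x_um > 0 and self.pitch_y_um > 0):
            raise ValueError("pixel pitch must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def physical_width_um(self) -> float:
        return self.width * self.pitch_x_um

    @property
    def physical_height_um(self) -> float:
        return self.height * self.pitch_y_um

    @property
    def area_mm2(self) -> float:
        return self.physical_width_um * self.physical_height_um / 1e6


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a 2-D uint8 grayscale array.

    RGB inputs are collapsed with standard luma weights; images written by
    :func:`write_image` (three identical channels) round-trip bit-exactly.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        if arr.shape[2] >= 3 and np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(
            arr[..., 0], arr[..., 2]
        ):
            arr = arr[..., 0]
        else:
            arr = np.clip(arr[..., :3].astype(float) @ _LUMA, 0, 255).round().astype(np.uint8)
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_image(pixels: np.ndarray, path: str | Path) -> Path:
    """Write a grayscale raster as RGB with three identical channels.

    Annotation tools (labelImg) expect depth-3 images; replicating the channel
    keeps the file compatible while the round-trip stays lossless.
    """
    path = Path(path)
    arr = np.asarray(pixels, dtype=np.uint8)
    rgb = np.repeat(arr[..., None], 3, axis=2)
    Image.fromarray(rgb).save(path)
    return path


# ---------------------------------------------------------------------------
# Pascal VOC XML (labelImg dialect)
# ---------------------------------------------------------------------------


def _require(parent: ET.Element, tag: str, path: str | Path) -> ET.Element:
    el = parent.find(tag)
    if el is None:
        raise ValueError(f"{path}: missing <{tag}> element")
    return el


def read_voc(path: str | Path) -> list[BoundingBox]:
    """Parse a VOC annotation file into internal-convention boxes.

    labelImg writes 1-based inclusive coordinates; they map to the internal
    0-based half-open convention as (xmin-1, ymin-1, xmax, ymax).
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed XML ({exc})") from exc
    boxes = []
    for obj in root.iter("object"):
        bnd = _require(obj, "bndbox", path)
        coords = {}
        for tag in ("xmin", "ymin", "xmax", "ymax"):
            coords[tag] = int(round(float(_require(bnd, tag, path).text)))
        boxes.append(
            BoundingBox(coords["xmin"] - 1, coords["ymin"] - 1, coords["xmax"], coords["ymax"])
        )
    return boxes


def write_voc(
    boxes: Sequence[BoundingBox],
    image_width: int,
    image_height: int,
    path: str | Path,
    *,
    filename: str | None = None,
    label: str = "stomata",
) -> Path:
    """Write boxes as labelImg-style VOC XML (1-based inclusive coordinates)."""
    path = Path(path)
    for b in boxes:
        if b.x_min < 0 or b.y_min < 0 or b.x_max > image_width or b.y_max > image_height:
            raise ValueError(
                f"box {b.as_tuple()} outside image bounds {image_width}x{image_height}"
            )
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(path.parent.name)
    ET.SubElement(root, "filename").text = filename or path.with_suffix(".png").name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(image_width)
    ET.SubElement(size, "height").text = str(image_height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for b in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(b.x_min + 1)
        ET.SubElement(bnd, "ymin").text = str(b.y_min + 1)
        ET.SubElement(bnd, "xmax").text = str(b.x_max)
        ET.SubElement(bnd, "ymax").text = str(b.y_max)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")
    return path


# ---------------------------------------------------------------------------
# Detections CSV
# ---------------------------------------------------------------------------


def write_detections_csv(
    detections: Iterable[tuple[str, Detection]], path: str | Path
) -> Path:
    """Write (source_id, Detection) pairs to CSV; lossless round-trip.

    Scores are serialized with full repr precision (>= 6 significant digits).
    """
    rows = [
        {
            "source_id": sid,
            "x_min": d.box.x_min,
            "y_min": d.box.y_min,
            "x_max": d.box.x_max,
            "y_max": d.box.y_max,
            "score": repr(float(d.score)),
        }
        for sid, d in detections
    ]
    df = pd.DataFrame(rows, columns=DETECTIONS_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_detections_csv(path: str | Path) -> list[tuple[str, Detection]]:
    df = pd.read_csv(path, dtype={"source_id": str})
    missing = [c for c in DETECTIONS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        box = BoundingBox(int(row.x_min), int(row.y_min), int(row.x_max), int(row.y_max))
        out.append((str(row.source_id), Detection(box, float(row.score))))
    return out
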