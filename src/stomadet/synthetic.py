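"""Synthetic leaf-imprint micrograph generator with known ground truth.

Emulates nail-varnish imprint micrographs of oil-palm abaxial epidermis:
a bright, gently textured background with dark-rimmed elliptical stomata
whose per-image count and horizontal size follow the per-age-group summary
statistics of the study populations (presets A-D).  Every image carries its
exact ground truth, so the whole detection pipeline is testable without any
real micrographs.

Counts are drawn from a rounded normal truncated at zero (only mean and sd
are reported for the real populations; a distribution had to be chosen).
Sizes are per-stoma normal draws of the horizontal end-to-end length in um.
Stomata are rendered axis-aligned, major axis horizontal, so the horizontal
box extent recovers the drawn size exactly up to pixel quantization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import BoundingBox, Micrograph, write_image, write_voc

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PRESETS",
    "preset",
    "generate_micrograph",
    "generate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    image_width_px: int = 2048
    image_height_px: int = 1536
    physical_width_um: float = 1800.0
    physical_height_um: float = 1400.0
    count_mean: float = 200.0
    count_sd: float = 18.0
    size_mean_um: float = 34.41
    size_sd_um: float = 2.67
    aspect_ratio_range: tuple[float, float] = (1.2, 1.6)
    background_intensity: float = 200.0
    background_noise_sd: float = 5.0
    defocus_prob: float = 0.1
    brightness_shift_prob: float = 0.1
    overlap_iou_cap: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_width_px, self.image_height_px) <= 0:
            raise ValueError("image dimensions must be positive")
        if min(self.physical_width_um, self.physical_height_um) <= 0:
            raise ValueError("physical dimensions must be positive")
        if self.count_sd < 0 or self.size_sd_um < 0:
            raise ValueError("standard deviations must be non-negative")
        for p in (self.defocus_prob, self.brightness_shift_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.aspect_ratio_range
        if not (0 < lo <= hi):
            raise ValueError("invalid aspect_ratio_range")

    @property
    def pitch_x_um(self) -> float:
        return self.physical_width_um / self.image_width_px

    @property
    def pitch_y_um(self) -> float:
        return self.physical_height_um / self.image_height_px


@dataclass
class GroundTruth:
    """Simulated analogue of manual annotation: boxes plus true sizes."""

    boxes: list[BoundingBox] = field(default_factory=list)
    sizes_um: list[float] = field(default_factory=list)
    requested_count: int = 0

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.sizes_um):
            raise ValueError("boxes and sizes_um must align")

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def complete(self) -> bool:
        """False when placement could not fit all requested stomata."""
        return len(self.boxes) == self.requested_count


# Per-age-group presets: per-image stomata count (mean, sd) and horizontal
# stoma size in um (mean, sd).  D shares C's biology but emulates a different
# microscope: 4x objective field 1589 um x 1192 um, darker illumination.
PRESETS: dict[str, GeneratorConfig] = {
    "A": GeneratorConfig(count_mean=107, count_sd=12, size_mean_um=31.82, size_sd_um=2.64),
    "B": GeneratorConfig(count_mean=200, count_sd=18, size_mean_um=34.41, size_sd_um=2.67),
    "C": GeneratorConfig(count_mean=208, count_sd=16, size_mean_um=43.01, size_sd_um=3.51),
    "D": GeneratorConfig(
        count_mean=208,
        count_sd=16,
        size_mean_um=43.01,
        size_sd_um=3.51,
        physical_width_um=1589.0,
        physical_height_um=1192.0,
        background_intensity=170.0,
        background_noise_sd=7.0,
    ),
}


def preset(group: str) -> GeneratorConfig:
    """Return the generator configuration for age-group preset A, B, C or D."""
    key = str(group).upper()
    if key not in PRESETS:
        raise ValueError(f"unknown preset {group!r}; valid presets: {sorted(PRESETS)}")
    return PRESETS[key]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _background(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height_px, cfg.image_width_px
    # low-frequency texture: coarse noise grid bilinearly upsampled
    ch, cw = max(h // 64, 2), max(w // 64, 2)
    coarse = rng.normal(0.0, 1.0, size=(ch + 1, cw + 1))
    tex = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)[:h, :w]
    img = cfg.background_intensity + 1.5 * cfg.background_noise_sd * tex
    img += rng.normal(0.0, cfg.background_noise_sd, size=(h, w))
    return img


def _render_stoma(
    img: np.ndarray,
    cx: float,
    cy: float,
    a: float,
    b: float,
    rim_level: float,
    pore_level: float,
) -> None:
    """Composite one stoma: dark elliptical guard-cell rim, brighter pore slit."""
    h, w = img.shape
    x0, x1 = max(int(cx - a) - 2, 0), min(int(cx + a) + 3, w)
    y0, y1 = max(int(cy - b) - 2, 0), min(int(cy + b) + 3, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    # pixel centers at k + 0.5
    dx = (xs + 0.5 - cx) / a
    dy = (ys + 0.5 - cy) / b
    r = np.sqrt(dx * dx + dy * dy)
    edge = 1.2 / min(a, b)  # anti-aliasing width in normalized radius units
    alpha = np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)  # 0.5 exactly on boundary
    # pore: horizontal slit at 0.55 a x 0.30 b
    rp = np.sqrt((dx / 0.55) ** 2 + (dy / 0.30) ** 2)
    pore = np.clip((1.0 - rp) / (edge / 0.3) + 0.5, 0.0, 1.0)
    level = rim_level + (pore_level - rim_level) * pore
    patch = img[y0:y1, x0:x1]
    patch[:] = patch * (1.0 - alpha) + level * alpha


def _pairwise_iou_ok(
    box: tuple[int, int, int, int], placed: np.ndarray, cap: float
) -> bool:
    if placed.size == 0:
        return True
    x0 = np.maximum(placed[:, 0], box[0])
    y0 = np.maximum(placed[:, 1], box[1])
    x1 = np.minimum(placed[:, 2], box[2])
    y1 = np.minimum(placed[:, 3], box[3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    if not inter.any():
        return True
    area = (box[2] - box[0]) * (box[3] - box[1])
    areas = (placed[:, 2] - placed[:, 0]) * (placed[:, 3] - placed[:, 1])
    iou = inter / (area + areas - inter)
    return bool(np.all(iou <= cap))


def generate_micrograph(
    config: GeneratorConfig, seed: int
) -> tuple[Micrograph, GroundTruth]:
    """Render one micrograph with exact ground truth; deterministic per (config, seed).

    The per-image stoma count is a rounded normal draw truncated at zero.
    Placement is rejection sampling with a pairwise-IoU cap (stomata on the
    epidermis do not overlap); if the budget of retries is exhausted the image
    carries fewer stomata and ``GroundTruth.complete`` is False.
    """
    rng = np.random.default_rng(seed)
    h, w = config.image_height_px, config.image_width_px
    img = _background(config, rng)

    n = int(round(rng.normal(config.count_mean, config.count_sd))) if config.count_sd > 0 else int(
        round(config.count_mean)
    )
    n = max(n, 0)

    boxes: list[BoundingBox] = []
    sizes: list[float] = []
    placed = np.empty((0, 4), dtype=np.int64)
    attempts_left = max(60 * n, 1)
    while len(boxes) < n and attempts_left > 0:
        attempts_left -= 1
        s_um = rng.normal(config.size_mean_um, config.size_sd_um)
        s_um = max(s_um, 0.3 * config.size_mean_um)
        a = s_um / config.pitch_x_um / 2.0
        aspect = rng.uniform(*config.aspect_ratio_range)
        b = (s_um / aspect) / config.pitch_y_um / 2.0
        if 2 * a + 4 >= w or 2 * b + 4 >= h:
            continue
        cx = rng.uniform(a + 2, w - a - 2)
        cy = rng.uniform(b + 2, h - b - 2)
        box = (
            int(round(cx - a)),
            int(round(cy - b)),
            int(round(cx + a)),
            int(round(cy + b)),
        )
        if not _pairwise_iou_ok(box, placed, config.overlap_iou_cap):
            continue
        rim = config.background_intensity - rng.uniform(95, 120)
        pore = config.background_intensity - rng.uniform(25, 45)
        _render_stoma(img, cx, cy, a, b, rim, pore)
        boxes.append(BoundingBox(*box))
        sizes.append(float(s_um))
        placed = np.vstack([placed, np.array(box, dtype=np.int64)])

    defocused = rng.uniform() < config.defocus_prob
    if defocused:
        img = ndimage.gaussian_filter(img, sigma=2.0)
    brightness = 1.0
    if rng.uniform() < config.brightness_shift_prob:
        brightness = rng.uniform(0.7, 1.35)
        img = img * brightness

    pixels = np.clip(img, 0, 255).round().astype(np.uint8)
    mg = Micrograph(
        pixels=pixels,
        pitch_x_um=config.pitch_x_um,
        pitch_y_um=config.pitch_y_um,
        source_id=f"synthetic_{seed}",
        metadata={
            "seed": seed,
            "requested_count": n,
            "placed_count": len(boxes),
            "defocused": defocused,
            "brightness_factor": round(float(brightness), 4),
        },
    )
    return mg, GroundTruth(boxes=boxes, sizes_um=sizes, requested_count=n)


def derive_image_seeds(master_seed: int, n_images: int) -> list[int]:
    """Deterministic, collision-resistant per-image seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_images, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_dataset(
    config: GeneratorConfig,
    n_images: int,
    seed: int,
    out_dir: str | Path,
    *,
    prefix: str = "img",
) -> Path:
    """Write ``n_images`` (PNG, VOC XML) pairs plus a manifest CSV; returns manifest path."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for i, img_seed in enumerate(derive_image_seeds(seed, n_images)):
        mg, gt = generate_micrograph(config, img_seed)
        stem = f"{prefix}_{i:04d}"
        write_image(mg.pixels, out_dir / f"{stem}.png")
        write_voc(gt.boxes, mg.width, mg.height, out_dir / f"{stem}.xml", filename=f"{stem}.png")
        rows.append({"path": f"{stem}.png", "n_stomata": len(gt), "seed": img_seed})
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "n_stomata", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def scaled_config(cfg: GeneratorConfig, factor: float) -> GeneratorConfig:
    """Shrink image area (and expected count) by ``factor`` keeping pixel pitch.

    Used for desk-scale experiments: stomata keep their size and local density
    while per-image cost drops.
    """
    return replace(
        cfg,
        image_width_px=int(round(cfg.image_width_px * factor)),
        image_height_px=int(round(cfg.image_height_px * factor)),
        physical_width_um=cfg.physical_width_um * factor,
        physical_height_um=cfg.physical_height_um * factor,
        count_mean=cfg.count_mean * factor * factor,
        count_sd=max(cfg.count_sd * factor, 1.0),
    )
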