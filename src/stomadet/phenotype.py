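"""Stomatal phenotypes from detections: density, size, and group comparison.

Density is the stomata count divided by the imaged leaf area in mm^2.  Size
is the horizontal end-to-end length of a stoma in um, i.e. the detected box
width converted through the x pixel pitch only (the x and y pitches differ
and are never averaged).  Group size statistics follow the assay protocol of
summarizing 150 randomly sampled stomata per group; groups are compared with
Welch's unequal-variance t-test on summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Micrograph
from .stitch import ImageDetections

__all__ = [
    "PhenotypeRecord",
    "GroupSummary",
    "density",
    "sizes",
    "phenotype_record",
    "sample_sizes",
    "welch_t_from_summary",
]


@dataclass
class PhenotypeRecord:
    source_id: str
    stomata_count: int
    density_per_mm2: float
    sizes_um: list[float]


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float


def density(image_detections: ImageDetections, micrograph: Micrograph) -> float:
    """Stomata per mm^2: count / (physical width x height in mm^2)."""
    area = micrograph.area_mm2
    if area <= 0:
        raise ValueError("micrograph lacks physical calibration")
    return len(image_detections) / area


def sizes(image_detections: ImageDetections, micrograph: Micrograph) -> list[float]:
    """Horizontal extents of detected boxes in um (x pitch only)."""
    return [d.box.width * micrograph.pitch_x_um for d in image_detections.detections]


def phenotype_record(image_detections: ImageDetections, micrograph: Micrograph) -> PhenotypeRecord:
    return PhenotypeRecord(
        source_id=image_detections.source_id,
        stomata_count=len(image_detections),
        density_per_mm2=density(image_detections, micrograph),
        sizes_um=sizes(image_detections, micrograph),
    )


def sample_sizes(
    all_sizes: list[float], k: int = 150, seed: int = 0, group: str = ""
) -> GroupSummary:
    """Mean/sd of ``k`` sizes sampled without replacement from the pooled group.

    If the pool holds fewer than ``k`` stomata the whole pool is used (n in the
    returned summary says which happened).
    """
    pool = np.asarray(all_sizes, dtype=float)
    if pool.size == 0:
        raise ValueError("empty size pool")
    if pool.size <= k:
        sample = pool
    else:
        rng = np.random.default_rng(seed)
        sample = rng.choice(pool, size=k, replace=False)
    return GroupSummary(
        group=group,
        n=int(sample.size),
        mean=float(sample.mean()),
        sd=float(sample.std(ddof=1)) if sample.size > 1 else 0.0,
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t-test from group summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).  With both sds zero the
    comparison degenerates: t = 0, p = 1 for equal means, t = +/-inf, p = 0
    otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1 = sd1 * sd1 / n1
    v2 = sd2 * sd2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.inf) * np.sign(mean1 - mean2), float(n1 + n2 - 2), 0.0
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
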