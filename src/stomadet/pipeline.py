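"""End-to-end pipeline: generate -> tile -> augment -> train -> detect -> evaluate -> phenotype.

One :class:`PipelineConfig` drives every stage; each random operation's seed
is derived deterministically from the master seed, and every artifact
directory is stamped with a hash of the configuration so reruns are
attributable.  All outputs live under one run directory:

    dataset/train/, dataset/test/   images + VOC XML + manifest
    checkpoint/                     weights, config snapshot, training log
    detections.csv                  stitched full-image detections
    evaluation.json                 precision/recall (+ mAP) on the test set
    phenotype.json                  per-image counts/densities, group summary
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import augment as aug
from .detector import TrainConfig, train
from .evaluate import mean_average_precision, precision_recall
from .io import read_image, read_voc, write_detections_csv
from .phenotype import phenotype_record, sample_sizes
from .stitch import detect_full_image
from .synthetic import GeneratorConfig, derive_image_seeds, generate_micrograph
from .tiling import split_fixed, tile_annotations

logger = logging.getLogger("stomadet")

__all__ = ["PipelineConfig", "run_pipeline", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    n_train_images: int = 8
    n_test_images: int = 8
    tile_w: int = 512
    tile_h: int = 512
    overlap_x: int = 120
    overlap_y: int = 40
    min_fraction: float = 0.5
    augment_fraction: float = 0.15
    val_fraction: float = 0.2
    eval_mode: str = "overlap"
    nms_iou: float = 0.01
    sample_k: int = 150
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["aspect_ratio_range"] = list(self.generator.aspect_ratio_range)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "aspect_ratio_range" in gen:
            gen["aspect_ratio_range"] = tuple(gen["aspect_ratio_range"])
        tc = dict(d.pop("train_config", {}))
        return PipelineConfig(
            generator=GeneratorConfig(**gen), train_config=TrainConfig(**tc), **d
        )


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _derived_seeds(master: int, n: int) -> list[int]:
    state = np.random.SeedSequence([master, 0xC0FFEE]).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def build_training_tiles(
    config: PipelineConfig, image_seeds: list[int]
) -> list[tuple[np.ndarray, list]]:
    """Generate training micrographs and project ground truth onto fixed tiles."""
    tiles = []
    for s in image_seeds:
        mg, gt = generate_micrograph(config.generator, s)
        for spec in split_fixed(mg, config.tile_w, config.tile_h):
            boxes = tile_annotations(gt.boxes, spec, config.min_fraction)
            tiles.append((spec.crop(mg.pixels), boxes))
    return tiles


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns a summary dict (also written as report.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    (out / "config.json").write_text(json.dumps({"hash": chash, **config.to_dict()}, indent=2))
    stage = "generate"
    try:
        seeds = _derived_seeds(config.seed, 4)
        train_seeds = derive_image_seeds(seeds[0], config.n_train_images)
        test_seeds = derive_image_seeds(seeds[1], config.n_test_images)

        logger.info("generate: %d train + %d test images", len(train_seeds), len(test_seeds))
        tiles = build_training_tiles(config, train_seeds)
        n_objects = sum(len(b) for _, b in tiles)
        logger.info("tile: %d tiles, %d stomata objects", len(tiles), n_objects)

        stage = "augment"
        if config.augment_fraction > 0:
            expanded, report = aug.augment_dataset(
                tiles, config.augment_fraction, aug.DEFAULT_SPECS, seed=seeds[2]
            )
            tiles = [(img, boxes) for img, boxes, _ in expanded]
            logger.info(
                "augment: %d -> %d tiles, %d -> %d objects",
                report["tiles_before"],
                report["tiles_after"],
                report["objects_before"],
                report["objects_after"],
            )
        else:
            report = {"tiles_after": len(tiles), "objects_after": n_objects}

        stage = "train"
        rng = np.random.default_rng(seeds[2])
        order = rng.permutation(len(tiles))
        n_val = max(1, int(round(config.val_fraction * len(tiles))))
        val_tiles = [tiles[i] for i in order[:n_val]]
        train_tiles = [tiles[i] for i in order[n_val:]]
        tc = replace(config.train_config, input_width=config.tile_w, input_height=config.tile_h)
        checkpoint = train(train_tiles, val_tiles, tc, checkpoint_dir=out / "checkpoint")
        logger.info("train: best val mAP@0.5 = %.3f at step %d", checkpoint.best_val_map, checkpoint.step)

        stage = "detect"
        detections_rows = []
        per_image = []
        records = []
        for s in test_seeds:
            mg, gt = generate_micrograph(config.generator, s)
            dets = detect_full_image(
                checkpoint,
                mg,
                config.tile_w,
                config.tile_h,
                config.overlap_x,
                config.overlap_y,
                tc.score_threshold,
                config.nms_iou,
            )
            per_image.append((dets.detections, gt.boxes))
            records.append(phenotype_record(dets, mg))
            detections_rows.extend((mg.source_id, d) for d in dets.detections)
        write_detections_csv(detections_rows, out / "detections.csv")

        stage = "evaluate"
        ev = precision_recall(per_image, mode=config.eval_mode)
        ap = mean_average_precision(per_image, iou=0.5)
        evaluation = {
            "mode": config.eval_mode,
            "precision_mean": ev.precision_mean,
            "precision_sd": ev.precision_sd,
            "recall_mean": ev.recall_mean,
            "recall_sd": ev.recall_sd,
            "tp": ev.true_positives,
            "fp": ev.false_positives,
            "fn": ev.false_negatives,
            "map_iou50": ap,
            "ap_interpolation": "all-point",
        }
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
        logger.info(
            "evaluate: precision %.3f recall %.3f mAP@0.5 %s",
            ev.precision_mean,
            ev.recall_mean,
            f"{ap:.3f}" if ap is not None else "n/a",
        )

        stage = "phenotype"
        pooled_sizes = [s for r in records for s in r.sizes_um]
        summary = sample_sizes(pooled_sizes, k=config.sample_k, seed=seeds[3], group="test")
        counts = [r.stomata_count for r in records]
        phen = {
            "per_image": [
                {
                    "source_id": r.source_id,
                    "stomata_count": r.stomata_count,
                    "density_per_mm2": r.density_per_mm2,
                }
                for r in records
            ],
            "count_mean": float(np.mean(counts)),
            "count_sd": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
            "size_sample": dataclasses.asdict(summary),
        }
        (out / "phenotype.json").write_text(json.dumps(phen, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary_doc = {
        "config_hash": chash,
        "tiles": report.get("tiles_after"),
        "objects": report.get("objects_after"),
        "best_val_map": checkpoint.best_val_map,
        "evaluation": evaluation,
        "phenotype": {k: phen[k] for k in ("count_mean", "count_sd", "size_sample")},
    }
    (out / "report.json").write_text(json.dumps(summary_doc, indent=2))
    return summary_doc


def load_annotated_dir(directory: str | Path) -> list[tuple[np.ndarray, list]]:
    """Read (image, boxes) pairs from a directory of PNG + VOC XML pairs."""
    directory = Path(directory)
    pairs = []
    for xml in sorted(directory.glob("*.xml")):
        png = xml.with_suffix(".png")
        if png.exists():
            pairs.append((read_image(png), read_voc(xml)))
    return pairs
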