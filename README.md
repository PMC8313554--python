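# stomadet

Automated stomata detection and density phenotyping for oil-palm
leaf-imprint micrographs.

Stomatal density — the number of stomata per mm² of leaf surface — is a key
selection trait for breeding drought-tolerant oil palms, but counting
stomata on microscope images of nail-varnish leaf imprints by hand takes
minutes per image. `stomadet` packages the automated alternative as a
reusable, fully testable toolkit:

1. **Synthetic data.** A generator renders imprint-style micrographs
   (1800 µm × 1400 µm at 2048 × 1536 px) with dark-rimmed elliptical stomata
   at the per-age-group count and size statistics of four study populations
   (seedlings A: 107 ± 12 stomata/image, 31.82 ± 2.64 µm; juveniles B:
   200 ± 18, 34.41 ± 2.67 µm; adults C: 208 ± 16, 43.01 ± 3.51 µm; D = C on
   a different microscope), with exact bounding-box ground truth written as
   Pascal VOC XML.
2. **Detection.** A single-class, anchor-based single-shot detector is
   trained on non-overlapping 512 × 512 tiles (12 per micrograph) with the
   loss `L = (L_c + α·L_l)/N` — softmax classification with 3:1
   hard-negative mining plus smooth-L1 localization over matched default
   boxes — under RMSprop with momentum, learning rate 0.003 decayed ×0.95
   every 100 steps, batch 20, L2 regularization and early stopping on
   validation mAP@0.5.
3. **Stitching.** Whole micrographs are split into 20 overlapping tiles
   (120 px horizontal / 40 px vertical overlap), predicted per tile at score
   threshold 0.2, remapped to global coordinates and merged with greedy NMS
   at IoU > 0.01 so each stoma keeps exactly one box.
4. **Evaluation & phenotyping.** Precision/recall with overlap-based or
   IoU ≥ 0.5 matching and single-class mAP; detections become densities
   (count / mm²) and sizes (horizontal box extent × x-pixel-pitch, in µm),
   summarized per group from 150 randomly sampled stomata and compared with
   Welch's t-test.

Photometric augmentation (Gaussian/bilateral blur, ×2 brighten/darken)
expands training tiles while preserving annotations.

## Worked example

Train on synthetic tiles from presets A and C, then phenotype fresh
seedling-preset micrographs:

```python
import numpy as np
import stomadet as sd
from stomadet.augment import DEFAULT_SPECS, augment_dataset
from stomadet.detector import TrainConfig, train
from stomadet.pipeline import PipelineConfig, build_training_tiles
from stomadet.synthetic import derive_image_seeds

tiles = []
for name, seed in (("A", 11), ("C", 13)):
    cfg = PipelineConfig(generator=sd.preset(name))
    tiles += build_training_tiles(cfg, derive_image_seeds(seed, 3))
expanded, _ = augment_dataset(tiles, 0.15, DEFAULT_SPECS, seed=2)
tiles = [(img, boxes) for img, boxes, _ in expanded]

rng = np.random.default_rng(0)
order = rng.permutation(len(tiles))
n_val = max(1, len(tiles) // 5)
ckpt = train(
    [tiles[i] for i in order[n_val:]],
    [tiles[i] for i in order[:n_val]],
    TrainConfig(max_steps=300, eval_interval=50, early_stop_patience=4, seed=7),
)
print(f"val mAP@0.5 = {ckpt.best_val_map:.3f}")

for s in derive_image_seeds(909, 3):
    mg, gt = sd.generate_micrograph(sd.preset("A"), s)
    dets = sd.detect_full_image(ckpt, mg)          # 20 tiles, NMS 0.01
    rec = sd.phenotype_record(dets, mg)
    print(f"{mg.source_id}: {rec.stomata_count} detected "
          f"({len(gt)} true), {rec.density_per_mm2:.1f} / mm2")
```

Output:

```
val mAP@0.5 = 0.996
synthetic_1637642055: 104 detected (108 true), 41.3 / mm2
synthetic_79167534: 107 detected (111 true), 42.5 / mm2
synthetic_869225620: 126 detected (132 true), 50.0 / mm2
```

The detector recovers per-image counts to within a few percent on this easy
synthetic imagery; densities are counts divided by the 2.52 mm² imaged area.

The same pipeline is scriptable from the shell:

```bash
stomadet generate --preset A --n-images 8 --seed 0 --out data/setA
stomadet run-all --config configs/smoke.yaml --out runs/smoke
```

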