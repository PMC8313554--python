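import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stomadet as sd
from stomadet.detector import TrainConfig, train
from stomadet.pipeline import PipelineConfig, build_training_tiles
from stomadet.synthetic import derive_image_seeds

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trained_checkpoint():
    """Desk-scale detector trained on synthetic tiles from presets A and C.

    Shared across behavioral tests; training is deterministic (seeded), takes
    under a minute on one CPU, and reaches near-perfect validation mAP on the
    easy synthetic imagery.
    """
    from stomadet.augment import DEFAULT_SPECS, augment_dataset

    tiles = []
    for name, seed in (("A", 11), ("C", 13)):
        cfg = PipelineConfig(generator=sd.preset(name))
        tiles += build_training_tiles(cfg, derive_image_seeds(seed, 3))
    expanded, _ = augment_dataset(tiles, 0.15, DEFAULT_SPECS, seed=2)
    tiles = [(img, boxes) for img, boxes, _ in expanded]
    rng = np.random.default_rng(0)
    order = rng.permutation(len(tiles))
    n_val = max(1, len(tiles) // 5)
    val = [tiles[i] for i in order[:n_val]]
    tr = [tiles[i] for i in order[n_val:]]
    config = TrainConfig(max_steps=300, eval_interval=50, early_stop_patience=4, seed=7)
    return train(tr, val, config)


@pytest.fixture(scope="session")
def blank_micrograph():
    """A stomata-free micrograph (background texture only)."""
    cfg = sd.GeneratorConfig(
        image_width_px=1024,
        image_height_px=512,
        physical_width_um=900.0,
        physical_height_um=466.67,
        count_mean=0.0,
        count_sd=0.0,
        defocus_prob=0.0,
        brightness_shift_prob=0.0,
    )
    mg, gt = sd.generate_micrograph(cfg, 99)
    assert len(gt) == 0
    return mg
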