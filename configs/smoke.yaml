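# Minimal end-to-end run: small images, tiny training budget (~20 s on one CPU).
generator:
  image_width_px: 512
  image_height_px: 512
  physical_width_um: 450.0
  physical_height_um: 450.0
  count_mean: 22
  count_sd: 3
  size_mean_um: 34.0
  size_sd_um: 2.7
  aspect_ratio_range: [1.2, 1.6]
  background_intensity: 200.0
  background_noise_sd: 5.0
  defocus_prob: 0.0
  brightness_shift_prob: 0.0
  overlap_iou_cap: 0.05
  seed: 0
train_config:
  max_steps: 120
  eval_interval: 40
  early_stop_patience: 3
  batch_size: 8
  seed: 1
n_train_images: 6
n_test_images: 3
tile_w: 512
tile_h: 512
augment_fraction: 0.2
seed: 42
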