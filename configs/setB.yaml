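# Desk-scale run emulating test set B: generator parameterized from the
# per-age-group count/size statistics; 135 test micrographs.
generator:
  image_width_px: 2048
  image_height_px: 1536
  physical_width_um: 1800.0
  physical_height_um: 1400.0
  count_mean: 200
  count_sd: 18
  size_mean_um: 34.41
  size_sd_um: 2.67
  aspect_ratio_range:
  - 1.2
  - 1.6
  background_intensity: 200.0
  background_noise_sd: 5.0
  defocus_prob: 0.1
  brightness_shift_prob: 0.1
  overlap_iou_cap: 0.05
  seed: 0
train_config:
  initial_lr: 0.003
  decay_factor: 0.95
  decay_steps: 100
  batch_size: 20
  n_classes: 1
  l2_weight: 0.0001
  alpha: 1.0
  score_threshold: 0.2
  match_iou: 0.5
  neg_pos_ratio: 3
  rmsprop_decay: 0.9
  momentum: 0.9
  max_steps: 500
  eval_interval: 50
  early_stop_patience: 4
  input_width: 512
  input_height: 512
  seed: 0
n_train_images: 8
n_test_images: 135
tile_w: 512
tile_h: 512
overlap_x: 120
overlap_y: 40
min_fraction: 0.5
augment_fraction: 0.15
val_fraction: 0.2
eval_mode: overlap
nms_iou: 0.01
sample_k: 150
seed: 86
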