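# Full-scale training recipe (GPU-scale data volume; not exercised in CI).
# Expects a processed-patch directory with a manifest.csv produced by the
# preprocessing pipeline (see README).

network:
  base_channels: 64
  variant: enhanced
  dropout_rate: 0.1
  seed: 0

train:
  epochs: 200
  batch_size: 4
  lr0: 0.001
  optimizer: AdamW
  weight_decay: 5.17e-4
  augment_flip: true
  augment_rotate: true
  augment_noise: true
  noise_sigma: 0.01
  seed: 0

loss_weights:
  w_bce: 0.2093
  w_dice: 0.4702
  w_iou: 0.3205
  alpha: 1.56

preprocess:
  hu_window: [-1000.0, 400.0]
  target_spacing: [2.0, 0.7, 0.7]   # (z, y, x) mm

pso:
  n_pop: 10
  max_iter: 20
  inertia: 0.7
  c1: 1.5
  c2: 1.5
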