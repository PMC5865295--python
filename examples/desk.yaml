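# Desk-scale end-to-end run: 10-species synthetic preset at 1/10 scale,
# mini backbone, two-phase training, all three evaluation surfaces.
seed: 1
dataset:
  preset: meliaceae10
  scale: 0.1
  image_size: 256
split:
  train_fraction: preset   # per-class reference fractions
  stratify_by: species
  unit: image
patch:
  patch_height: 256
  patch_width: 96
  resized_height: 64
  resized_width: 24
  train_quota_per_class: 64
  test_quota_per_class: 24
model:
  backbone: mini
  pooling: avg
  dropout: 0.5
training:
  batch_size: 8
  monitor: val
  val_fraction: 0.25
  phase1: {max_epochs: 30, learning_rate: 0.01, momentum: 0.9}
  phase2: {max_epochs: 50, learning_rate: 0.001, decay: 0.0005, early_stop_patience: 10}
evaluation:
  levels: [species, genus_clubbed, genus]
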