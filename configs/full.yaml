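# Full-scale recipe: 256x256 inputs, 20000 iterations, ~2600 pairs.
# This mirrors the original study configuration and is NOT intended for a
# single-CPU desk run; use configs/desk.yaml for that.
seed: 0
n_pairs: 2600
split: [0.8, 0.1, 0.1]

geometry: {}

simulation:
  image_size: [256, 256]

preprocessing:
  method: otsu
  connectivity: 8
  policy: largest

network:
  variant: uiu
  n_scales: 4
  inner_depths: [4, 3, 2, 2]
  base_channels: 16

training:
  input_size: 256
  learning_rate: 0.001
  batch_size: 2
  iterations: 20000
  loss: multi_bce

metrics:
  overlap_threshold: 0.3
  pass_through_tol: 1.0
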