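# Desk-scale end-to-end configuration: completes on one CPU in ~10 minutes.
# Every printed default of the full-scale recipe is kept (learning rate,
# batch size, 80:10:10 split); only the image size, network capacity and
# iteration budget are reduced.
seed: 0
n_pairs: 300
split: [0.8, 0.1, 0.1]

geometry: {}  # all defaults: 128 elements, 8 MHz, 10 Hz laser, 64 parallel rx

simulation:
  image_size: [128, 128]
  angle_range: [10, 45]
  gauges: [18, 23]

preprocessing:
  method: otsu
  connectivity: 8
  policy: largest

network:
  variant: uiu
  n_scales: 4
  inner_depths: [4, 3, 2, 2]
  base_channels: 8

training:
  input_size: 128
  learning_rate: 0.001
  batch_size: 2
  iterations: 800
  eval_every: 200
  loss: multi_bce

metrics:
  overlap_threshold: 0.3
  pass_through_tol: 1.0
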