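# Desk-scale defaults: small enough to train on one CPU in minutes.
optical:
  background_level: 1000.0
  pixel_size_um: 0.108
noise: {}
scene:
  n_frames: 8
  shape: [64, 64]
  particles:
    - {x: 32.0, y: 32.0, amplitude: 0.1, phase: 0.0}
denoiser:
  n_levels: 4
  base_channels: 8
  lstm_hidden_channels: 8
  kernel_size: 3
  in_frames: 8
training:
  lr0: 1.0e-3
  lr_decay: 0.5
  decay_every_epochs: 50
  epochs: 30
  batch: 4
  train_fraction: 0.7
  checkpoint_every: 5
  data:
    n_pairs: 24
    n_frames: 8
    shape: [32, 32]
seed: 0
out_dir: runs/desk
log_level: INFO
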