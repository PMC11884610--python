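# Published full-scale training protocol (multi-GPU scale; recorded for
# reference, not for desk execution): 1000 sequence pairs, 1000 epochs,
# minimum batch 32, initial lr 1e-4 halved every 50 epochs, 0.7/0.3
# train/validation split, checkpoints every 5 epochs, lowest-validation-loss
# model selected, targets from 100-adjacent-frame averages.
optical:
  background_level: 1000.0
  pixel_size_um: 0.108
noise: {}
scene:
  n_frames: 8
  shape: [512, 512]
  particles: []
denoiser:
  n_levels: 4
  base_channels: 64
  lstm_hidden_channels: 64
  kernel_size: 3
  in_frames: 4
training:
  lr0: 1.0e-4
  lr_decay: 0.5
  decay_every_epochs: 50
  epochs: 1000
  batch: 32
  train_fraction: 0.7
  checkpoint_every: 5
  data:
    n_pairs: 1000
    n_frames: 8
    shape: [512, 512]
seed: 0
out_dir: runs/published_scale
log_level: INFO
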