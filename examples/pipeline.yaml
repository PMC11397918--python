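# Small end-to-end pipeline configuration: 10 simulated frames,
# segmentation training included, all four staging tasks on phase spectra.
out: runs/demo
seed: 7
n_per_stage: 2
effect_scale: 2.0
seg:
  arch: unet
  encoder_widths: [8, 16, 32]
  input_shape: [96, 128]
  epochs: 20
  batch_size: 2
seg_ratios: [0.6, 0.2, 0.2]
clf:
  conv_channels: [4, 4, 4, 4]
  kernel_sizes: [5, 3, 3, 3]
  fc_widths: [32, 16, 8, 2]
  epochs: 2
clf_ratios: [0.6, 0.2, 0.2]
tasks: [geF1, geF2, geF3, geF4]
kinds: [phase]
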