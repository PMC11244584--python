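# Full lightweight variant: star backbone + grouped-conv neck + shared head
# + PIoUv2 box loss.  The backbone widths/depths and the neck fused widths
# below are the calibrated repository constants.
backbone:
  type: starnet
  stem_channels: 8
  stage_channels: [16, 32, 64, 128]   # doubling per stage
  stage_depths: [2, 8, 2, 2]
  dw_kernel: 5
neck:
  type: c2f_elc
head:
  type: detect_el
  norm_groups: 8
  reg_bins: 16
loss:
  box: piouv2
  lambda: 1.1
num_classes: 2
input_size: 640
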