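# Stock nano-scale baseline (DarkNet-style C2f backbone, plain C2f neck,
# per-level detection head, CIoU box loss).
backbone:
  type: darknet
neck:
  type: c2f
head:
  type: detect
loss:
  box: ciou
num_classes: 2
input_size: 640
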