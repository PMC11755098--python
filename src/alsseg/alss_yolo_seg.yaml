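# Default ALSS-YOLO-Seg graph: 25 layers (0-24).
# Backbone rows 1-10, FPN-style neck rows 11-23 with one MSCA attention
# block at layer 16, segmentation head at 24 fed by the 80/40/20-cell levels.
name: alss-yolo-seg
input_size: [640, 640, 3]
num_classes: 1
reg_max: 24
num_prototypes: 32
layers:
  - {index: 0, kind: input}
  - {index: 1, kind: conv, out_channels: 8, kernel: 3, stride: 2}
  - {index: 2, kind: conv, out_channels: 16, kernel: 3, stride: 2}
  - {index: 3, kind: conv, out_channels: 16, kernel: 3, stride: 1}
  - {index: 4, kind: conv, out_channels: 24, kernel: 3, stride: 1}
  - {index: 5, kind: alss, out_channels: 24, stride: 2}
  - {index: 6, kind: alss, out_channels: 48, stride: 1}
  - {index: 7, kind: alss, out_channels: 88, stride: 2}
  - {index: 8, kind: alss, out_channels: 88, stride: 1}
  - {index: 9, kind: alss, out_channels: 176, stride: 2}
  - {index: 10, kind: sppf, out_channels: 176}
  - {index: 11, kind: upsample}
  - {index: 12, kind: concat, sources: [11, 8], out_channels: 264}
  - {index: 13, kind: alss, out_channels: 88, stride: 1}
  - {index: 14, kind: upsample}
  - {index: 15, kind: concat, sources: [14, 6], out_channels: 136}
  - {index: 16, kind: msca}
  - {index: 17, kind: alss, out_channels: 48, stride: 1}
  - {index: 18, kind: conv, out_channels: 48, kernel: 3, stride: 2}
  - {index: 19, kind: concat, sources: [18, 13], out_channels: 136}
  - {index: 20, kind: alss, out_channels: 88, stride: 1}
  - {index: 21, kind: conv, out_channels: 88, kernel: 3, stride: 2}
  - {index: 22, kind: concat, sources: [21, 10], out_channels: 264}
  - {index: 23, kind: alss, out_channels: 176, stride: 1}
  - {index: 24, kind: segment, sources: [17, 20, 23]}
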