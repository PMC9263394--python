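# Default 29-channel motor-cortex montage: 12 sources, 8 detectors, 3 cm
# separation, source S1 anchored at Cz (10/20 system).  Geometry is metadata
# only; all analyses depend solely on ROI membership below.
n_channels: 29
n_sources: 12
n_detectors: 8
separation_cm: 3.0
anchor: Cz
rois:
  SMA_left: [1, 5, 6, 16]
  SMA_right: [1, 5, 7, 20]
  PMC_left: [17, 18, 19, 24, 26, 27]
  PMC_right: [21, 22, 23, 25, 28, 29]
  SM1_left: [2, 3, 8, 9, 12, 13]
  SM1_right: [2, 4, 10, 11, 14, 15]
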