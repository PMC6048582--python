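# 14-channel 10/20 montage (Emotiv EPOC layout) and its seven symmetric
# left/right channel pairs used for hemispheric asymmetry features.
channels:
  [AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4]
symmetric_pairs:
  - [AF3, AF4]
  - [F7, F8]
  - [F3, F4]
  - [FC5, FC6]
  - [T7, T8]
  - [P7, P8]
  - [O1, O2]
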