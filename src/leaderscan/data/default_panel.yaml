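# Default reporter-leader panel: Short/Long lengths crossed with three
# composition strata, three inserts each, plus three G-free controls.
# The numeric low-C / high-C / high-GC targets are this package's own
# calibration of the coarse strata; edit freely and pass via
# `leaderscan design --panel <file>`.
categories:
  Short-LoC:
    length: 24
    composition: {A: 0.30, C: 0.15, G: 0.35, T: 0.20}
  Short-HiC:
    length: 24
    composition: {A: 0.25, C: 0.35, G: 0.15, T: 0.25}
  Short-HiGC:
    length: 24
    composition: {A: 0.15, C: 0.35, G: 0.35, T: 0.15}
  Long-LoC:
    length: 148
    composition: {A: 0.30, C: 0.15, G: 0.35, T: 0.20}
  Long-HiC:
    length: 148
    composition: {A: 0.25, C: 0.35, G: 0.15, T: 0.25}
  Long-HiGC:
    length: 148
    composition: {A: 0.15, C: 0.35, G: 0.35, T: 0.15}
controls:
  CAU-1:
    length: 148
    composition: {A: 0.34, C: 0.33, T: 0.33}
    forbidden_bases: [G]
    n_sequences: 1
  CA-1:
    length: 148
    composition: {A: 0.50, C: 0.50}
    forbidden_bases: [G]
    n_sequences: 1
  CA-2:
    length: 148
    composition: {A: 0.50, C: 0.50}
    forbidden_bases: [G]
    n_sequences: 1
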