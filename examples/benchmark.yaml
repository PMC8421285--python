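# Two-ROI synthetic benchmark: three repeats of the middle b-value (R3)
# against one acquisition of each b-value (M3), compared with a one-sided
# rank-sum test. Needs >= 3 ROI pairs for the comparison, hence 3 ROIs here.
patch:
  benchmark:
    n_rois: 3
    vertices_per_roi: 100
    seed: 0
conditions: [R3, M3]
comparisons:
  - [M3, R3]
seed: 0
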