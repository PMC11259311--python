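# Reference desk-scale demo: 20x20 grid of 10 km cells, two years,
# 30 monitoring sites, 5 regions. All other parameters at defaults.
seed: 1
paths:
  out_dir: run1
model:
  n_trees: 300
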