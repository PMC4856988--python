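name: fig3c
description: >
  Eu/heterochromatin blocks: 300 light-green beads alternate with 100 pink
  beads; red factors bind pink, green factors bind light-green.
units: {sigma_nm: 30.0, kbp_per_bead: 3.0}
box_edge_sigma: 100.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: blocks
    n_beads: 5000
    blocks: [[300, lightgreen], [100, pink]]
species:
  - color: red
    count: 250
    activation_time: 10000.0
    affinity: {pink: 8.0}
  - color: green
    count: 250
    activation_time: 10000.0
    affinity: {lightgreen: 8.0}
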