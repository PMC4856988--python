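name: fig3b
description: >
  Gene deserts: blocks of 400 binding beads (blue background with one pink
  bead every 20) alternate with blocks of 100 non-binding gray beads; red
  factors bind blue weakly and pink strongly, never gray.
units: {sigma_nm: 30.0, kbp_per_bead: 3.0}
box_edge_sigma: 100.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: blocks
    n_beads: 5000
    spacing: 20
    blocks: [[400, binding], [100, gray]]
    binding_color: pink
    background_color: blue
species:
  - color: red
    count: 250
    activation_time: 10000.0
    affinity: {pink: 8.0, blue: 6.0}
analysis:
  janus_window_beads: 100
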