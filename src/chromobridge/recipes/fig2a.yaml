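name: fig2a
description: >
  Two-species toy model: one binding bead every 20, alternating pink and
  light-green along the fiber; 250 red factors bind pink and 250 green
  factors bind light-green (specific binding only).
units: {sigma_nm: 30.0, kbp_per_bead: 3.0}
box_edge_sigma: 100.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: alternating
    n_beads: 5000
    spacing: 20
    colors_cycle: [pink, lightgreen]
    background_color: blue
species:
  - color: red
    count: 250
    activation_time: 10000.0
    affinity: {pink: 8.0, blue: 6.0}
  - color: green
    count: 250
    activation_time: 10000.0
    affinity: {lightgreen: 8.0, blue: 6.0}
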