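name: fig3a
description: >
  Homogeneous control for domain formation: identical to fig1a (regularly
  spaced pink beads); pyramids appear in single runs but average out over
  many runs because clusters nucleate at random positions.
units: {sigma_nm: 30.0, kbp_per_bead: 3.0}
box_edge_sigma: 100.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: regular
    n_beads: 5000
    spacing: 20
    binding_color: pink
    background_color: blue
species:
  - color: red
    count: 250
    activation_time: 10000.0
    affinity: {pink: 8.0, blue: 6.0}
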