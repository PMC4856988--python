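name: fig3d
description: >
  Permanent loops: all beads pink and uniformly binding; anchors are bonded
  irreversibly into 324-bead loops separated by 300 unlooped beads with 150
  unlooped beads at each end.
units: {sigma_nm: 30.0, kbp_per_bead: 3.0}
box_edge_sigma: 100.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: uniform
    n_beads: 5000
    background_color: pink
    loops: {loop_beads: 324, gap_beads: 300, end_gap: 150}
species:
  - color: red
    count: 250
    activation_time: 10000.0
    affinity: {pink: 5.0}
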