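name: fig1a
description: >
  Single 5000-bead fiber (15 Mbp at 3 kbp/bead) with one pink high-affinity
  bead every 20, plus 250 red multivalent factors in a 3 um (100 sigma)
  periodic cube; binding switches on after 10^4 time units.
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
analysis:
  contact_threshold_sigma: 5.0
  bin_beads: 40
  cluster_cutoff_sigma: 3.0
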