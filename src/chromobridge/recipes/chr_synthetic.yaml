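name: chr_synthetic
description: >
  Human-chromosome-style two-protein run on a synthetically annotated
  15 Mbp region at 1 kbp/bead (placeholder fiber; the painted fiber is
  built at run time from the synthetic annotation by the painting
  pipeline). 300 red factors bind pink strongly and light-green weakly;
  3000 black proteins bind gray beads.
units: {sigma_nm: 20.8, kbp_per_bead: 1.0}
box_edge_sigma: 428.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: regular
    n_beads: 15000
    spacing: 20
    binding_color: pink
    background_color: blue
species:
  - color: red
    count: 300
    activation_time: 10000.0
    affinity: {pink: 8.0, lightgreen: 4.0}
  - color: black
    count: 3000
    activation_time: 10000.0
    affinity: {gray: 6.0}
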