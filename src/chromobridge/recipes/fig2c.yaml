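name: fig2c
description: >
  Five factor species (500 each) binding 7.1 kT to five sets of cognate
  sites scattered randomly along 20 identical 2000-bead fibers (6 Mbp each).
units: {sigma_nm: 30.0, kbp_per_bead: 3.0}
box_edge_sigma: 100.0
run_time: 50000.0
sample_interval: 1000.0
fibers:
  - pattern: scattered
    n_beads: 2000
    copies: 20
    species_colors: [red, green, darkblue, purple, black]
    per_color_fraction: 0.01
    background_color: blue
species:
  - {color: red,      count: 500, activation_time: 10000.0, affinity: {red: 7.1}}
  - {color: green,    count: 500, activation_time: 10000.0, affinity: {green: 7.1}}
  - {color: darkblue, count: 500, activation_time: 10000.0, affinity: {darkblue: 7.1}}
  - {color: purple,   count: 500, activation_time: 10000.0, affinity: {purple: 7.1}}
  - {color: black,    count: 500, activation_time: 10000.0, affinity: {black: 7.1}}
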