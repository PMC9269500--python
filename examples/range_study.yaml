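# Three-energy range study: CSDA vs Monte Carlo vs synthetic-image ranges.
material: abls
energies: [6.0, 9.0, 12.0]
histories: 100000
field_width: 6.0
cell_size: 0.05
v_cut: 0.3
seed: 1
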