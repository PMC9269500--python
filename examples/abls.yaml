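# Alcohol-based liquid scintillator: 2-ethoxyethanol and water mixed 7:3
# by volume; the bulk density is the measured value for the mixture.
name: AbLS
basis: volume
density: 0.945
component_densities: [0.930, 0.998]
components:
  - {formula: C4H10O2, proportion: 7}
  - {formula: H2O, proportion: 3}
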