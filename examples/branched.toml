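[metadata]
author = "bstkit"
version = "1.0"
name = "branched pathway with dual feedback"

[model]
dynamic_species = ["A", "B", "C", "D", "E"]
static_species = ["E3", "E4"]
reactions = ["r0::[] --> A", "r1::A --> B", "r2::B --> C", "r3::C --> D", "r4::C --> E", "r5::D --> []", "r6::E --> []"]
kinetics = ["r1::A^1.0,E^-0.5", "r2::B^1.0,D^-0.5", "r3::C^1.0,E3^1.0", "r4::C^1.0,E4^1.0", "r5::D^1.0", "r6::E^1.0"]
stoichiometry = []

[model.alpha]
r0 = 1.0
r1 = 1.0
r2 = 1.0
r3 = 1.0
r4 = 1.0
r5 = 1.0
r6 = 1.0

[model.initial]
A = 0.1
B = 0.1
C = 0.1
D = 0.1
E = 0.1

[model.static_values]
E3 = 1.0
E4 = 1.0
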