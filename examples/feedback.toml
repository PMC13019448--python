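[metadata]
author = "bstkit"
version = "1.0"
name = "feedback-inhibited linear pathway"

[model]
dynamic_species = ["X1", "X2", "X3", "X4", "X5"]
static_species = ["E1", "E2", "E3"]
reactions = ["r0::[] --> X1", "r1::X1 --> X2", "r2::X2 --> X3", "r3::X3 --> X4", "r4::X4 --> []", "r5::X3 --> X5"]
kinetics = ["r1::X1^1.0,X4^-0.5,E1^1.0", "r2::X2^1.0,E2^1.0", "r3::X3^1.0,E3^1.0", "r4::X4^1.0", "r5::X3^1.0"]
stoichiometry = []

[model.alpha]
r0 = 0.0
r1 = 10.0
r2 = 10.0
r3 = 10.0
r4 = 3.0
r5 = 0.1

[model.initial]
X1 = 0.1
X2 = 0.1
X3 = 0.1
X4 = 0.1
X5 = 0.1

[model.static_values]
E1 = 1.0
E2 = 1.0
E3 = 1.0
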