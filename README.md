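# bstkit

A Python toolkit for building, simulating, and analyzing **Biochemical
Systems Theory (BST)** models of metabolic and regulatory networks — the
S-system power-law formalism — with declarative model files, pulsed-input ODE
simulation, steady-state computation, and native Morris and Sobol global
sensitivity analysis. It is aimed at systems biologists and metabolic
engineers who want the stoichiometric and kinetic-order structure of their
model exposed as plain matrices they can inspect and perturb.

## The model

A network with `n` dynamic species `x`, `m` static species `x_s` (enzymes,
fixed pools), and `p` reactions evolves as

```
dx/dt = S · r(x, x_s) + u(t),     r_k = α_k · ∏_j X_j^G[j,k]
```

where `S ∈ R^{n×p}` is the stoichiometric matrix, `G ∈ R^{(n+m)×p}` the
kinetic-order matrix (positive order = activation, negative = inhibition,
zero = no dependence), `α ≥ 0` the rate constants, and `u(t)` an optional
external input. This generalizes the classical two-term S-system

```
dX_i/dt = α_i ∏ X_j^g_ij − β_i ∏ X_j^h_ij,
```

whose steady state is linear in logarithmic coordinates; `bstkit` solves it
both analytically (`solve_loglinear`) and by dynamic settling
(`steadystate`), and the two routes cross-check each other in the test
suite. Sensitivity of a scalar output (e.g. the time-integrated product
concentration `J = ∫ X4 dt`) to rate constants and kinetic orders is
quantified by Morris elementary-effects screening (μ, μ*, σ²) and Sobol
variance decomposition (S1 via the Saltelli-2010 estimator, ST via the
Jansen estimator, bootstrap confidence intervals), both implemented in the
package over a scrambled low-discrepancy design.

## Worked example

The repository ships a five-species feedback-inhibited pathway
(`examples/feedback.toml`): X1 → X2 → X3 → X4 with a branch X3 → X5, unit
enzymes E1–E3 on r1–r3, and end-product feedback of X4 on r1 with kinetic
order −0.5. X1 production is driven by a pulsed input (baseline 1, a high
pulse u1 = 10 on t ∈ [5, 15], a medium pulse u1 = 5 on t ∈ [25, 35]).

```python
import numpy as np
from bstkit import evaluate, sobol, make_objective
from bstkit.fixtures import feedback_pathway_model, feedback_parameter_map

model, pulses = feedback_pathway_model()
traj = evaluate(model, (0, 50), input=pulses)
print(f"peak X4 = {traj.column('X4').max():.2f}")

pmap = feedback_parameter_map()   # 6 rate parameters ±50%, feedback order in [-2, 0]
J = make_objective(model, pmap, input=pulses, tspan=(0, 20), species="X4")
res = sobol(J, pmap.bounds, base_samples=256, seed=7, names=pmap.names)
for name in res.ranking()[:3]:
    i = res.names.index(name)
    print(f"{name}: S1={res.S1[i]:.2f} ST={res.ST[i]:.2f}")
```

prints

```
peak X4 = 3.30
alpha_r4: S1=0.49 ST=0.52
alpha_r0: S1=0.39 ST=0.46
g_X4_r1: S1=-0.00 ST=0.00
```

The product peaks at 3.30 during the high pulse — feedback throttles entry
into the pathway as X4 accumulates. The variance of the integrated product
exposure is dominated by how fast X4 is removed (the degradation constant
`alpha_r4`) and how much material enters the pathway (the source amplitude
`alpha_r0`); the intermediate conversion steps and even the feedback order
itself barely matter. The small S1→ST gaps indicate mild parameter
interactions, as expected for multiplicative kinetics.

The same analyses run from the shell:

```sh
bstkit simulate --model examples/feedback.toml --tspan 0 50 \
    --input examples/feedback_pulses.json --out traj.csv
bstkit sobol --model examples/feedback.toml --bounds examples/feedback_bounds.json \
    --input examples/feedback_pulses.json --samples 1024 --seed 42 --out sobol.csv
```

## Layout

- `bstkit.model_core` — `BSTModel`, reaction/kinetics records, matrix
  assembly, validation, classical-form conversion
- `bstkit.io_formats` — TOML and BST text dialects, JSON model archive
- `bstkit.simulate` — rates, ODE integration with pulse segmentation,
  steady states (settling + log-linear)
- `bstkit.sensitivity` — Morris, Sobol, parameter maps, the performance
  integral
- `bstkit.fixtures` — reference pathways and random-model generators
- `bstkit.cli` — `bstkit build|simulate|steadystate|morris|sobol`

See `docs/methods.md` for the numerical choices and their rationale.
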