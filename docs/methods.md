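# Methods

## Model representation

A model is a set of named dynamic species (the state vector), static species
(externally fixed concentrations that appear in rate laws but never change),
and reactions. Connectivity and kinetics are kept separate: reaction records
(reactants/products with positive coefficients) compile into the
stoichiometric matrix `S` with the convention *reactants negative, products
positive*, and kinetics records ((species, exponent) pairs) compile into the
kinetic-order matrix `G`. Row order in `G` is dynamic species first, then
static species, each in declaration order; this ordering is fixed
package-wide. Stoichiometry overrides replace the computed `S` entry
verbatim, and an override of 0 is legal — it models a species that
catalyzes a reaction (appears in `G`) without mass flow. Kinetic exponents
are always explicit in the in-memory records; only the file readers apply
the mass-action-like default of 1.0 for unannotated species, so the core
stays unambiguous. Reactions with no kinetic dependencies (all-zero `G`
column) are permitted and give constant-rate sources.

The classical two-term form (one aggregate production and one aggregate
consumption power law per species) is available for the representable
subclass: exactly one producing and one consuming reaction per species, with
stoichiometric coefficients ±1 and strictly positive rate constants (the
log transform requires them). Anything else raises a "not classically
representable" error rather than silently aggregating.

## Rate evaluation and integration

Rates are evaluated as `α · exp(Gᵀ ln X̃)` where `X̃` is the concatenated
species vector floored at `ε = 1e-8`. The floor applies only inside the rate
law, never to the stored state: its sole purpose is to keep negative kinetic
orders (e.g. the −0.5 feedback) finite when a concentration starts at or
transiently touches zero. Factors with zero exponent contribute exactly 1
even at zero concentration.

Integration uses scipy's LSODA (stiff-capable, automatic method switching)
at `rtol = 1e-8`, `atol = 1e-10`, with a Radau fallback on failure. External
inputs are piecewise-constant pulse schedules (a baseline per channel plus
non-overlapping (start, stop, amplitude) pulses; the amplitude replaces the
baseline during the pulse). The integrator is restarted at every pulse edge:
adaptive steppers crossing a ×10 step input without segmentation lose
accuracy at the discontinuity. Default output grid: 1001 uniform points.

Steady states by dynamic settling integrate from `x0` over successively
doubled horizons until `‖dx/dt‖∞ < τ_abs + τ_rel·‖x‖∞` with defaults
`τ_abs = 1e-8`, `τ_rel = 1e-6`, `t_max = 1e6` (all overridable); failure to
converge raises an error carrying the last state and residual, which is the
signature of sustained oscillation or divergence rather than a bug. For
classical systems the steady state is also solved analytically:
`(Gc − Hc)_dyn · ln x = ln(β/α) − (Gc − Hc)_static · ln x_s`, a single
linear solve; a singular matrix means a degenerate steady state and is
reported as such. The test suite requires the two routes to agree to 1e-5
relative on a 50-system random ensemble.

## Sensitivity analysis

Both methods treat the model as a black-box scalar function, by default the
performance integral `J = ∫ X_species dt` computed by trapezoid on a dense
grid (≥2001 points). Parameters are addressed through a `ParameterMap`
(rate constants, kinetic orders, static values, initial conditions, or the
input-schedule scale); every evaluation applies the parameter vector to a
deep copy of the model, so evaluations are pure. Objective evaluations for
sensitivity use `rtol = 1e-6`, `atol = 1e-9` — `J` is a smooth integral
functional and the looser tolerance is far below the Monte Carlo resolution
while cutting run time several-fold. A failed evaluation is retried once at
tenfold tighter tolerance, then recorded as missing and excluded; more than
1% missing aborts the analysis.

**Morris.** Classic trajectory (not radial) design on a `p = 4`-level grid
of the unit hypercube with step `Δ = p/(2(p−1)) = 2/3`; base points are
drawn uniformly from the sub-grid from which a step stays inside the cube,
step direction is random per coordinate, and each of the `r` trajectories
yields one elementary effect per parameter,
`EE_k = (f(θ + Δ e_k·span) − f(θ))/Δ`, signed with respect to increasing
parameter value. Reported statistics: signed mean μ, mean absolute μ* (the
ranking statistic), and sample variance σ². Fixed seed ⇒ bit-identical
results.

**Sobol.** Saltelli design: base matrices `A`, `B` (N×d) drawn from a
seeded, scrambled Sobol' sequence (scipy.stats.qmc), plus `d` cross matrices
`A_B^(i)` — `N(d+2)` model evaluations. `S1` uses the Saltelli-2010
estimator `mean(f_B·(f_AB − f_A))/V`, `ST` the Jansen estimator
`mean((f_A − f_AB)²)/(2V)`. 95% confidence intervals come from a row
bootstrap (default 200 resamples; no extra model evaluations). A
zero-variance output reports all indices as 0 with a `degenerate` flag.
Note an estimator property checked in the tests: scaling the output leaves
both indices exactly unchanged; an additive shift cancels exactly for
Jansen's ST but only in expectation for the Saltelli S1 estimator.

## Reference pathways

The *feedback pathway* fixture is a five-species linear chain X1→X2→X3→X4
with a branch X3→X5, unit enzymes E1–E3 on r1–r3, and feedback order −0.5 of
X4 on r1. Rate constants: r1 = r2 = r3 = 10, r4 = 3, r5 = 0.1, r0 = 0 —
production of X1 is driven entirely through the pulse schedule (baseline 1,
pulse 10 on [5, 15], pulse 5 on [25, 35]). Initial conditions are 0.1 for
all species: strictly positive, small against the order-1–3 responses, and
fixed so the peak-response result is reproducible. Under this protocol X4
peaks at ≈3.3 during the high pulse.

The seven-parameter sensitivity study varies the five nonzero rate
constants at ±50% of nominal, the feedback order over [−2, 0], and — since
the source is an input, not a rate constant — a multiplicative scale on
u1(t) with nominal 1.0 and bounds [0.5, 1.5] standing in as the source-rate
parameter (`alpha_r0`). The output is `J = ∫₀²⁰ X4 dt` under the pulsed
input (the high pulse lies inside the window).

The *branched pathway* fixture (source→A→B→C, branch C→D|C→E, first-order
degradation of D and E, feedback of E on r1 and D on r2 at order −0.5) uses
rate constants of 1.0 throughout; with the branch enzymes E3, E4 as static
species, sweeping E3 ∈ [0.1, 5] at E4 = 1 redistributes flux monotonically
from the E branch to the D branch with a single crossing at E3 = 1. The
checks on this fixture are qualitative (monotonicity and crossing) by
design — they are properties of the topology, not of particular constants.

Random generators: `random_model` produces connected reaction graphs with
orders in [−1, 1] and rate constants in [0.5, 5] for structural/round-trip
property tests. `random_classical_system` additionally enforces a stable
steady state (consumption orders diagonally dominant: `Hc` diagonal in
[0.6, 1.0], couplings `O(0.3/n)`) so that dynamic settling provably has
something to settle to; this is the ensemble for the settling-vs-log-linear
cross-check.

## What the synthetic fixtures do and do not show

The fixtures exercise feedback inhibition, branch-point competition, pulsed
loading, and parameter sensitivity in small, well-conditioned networks with
smooth power-law kinetics. Passing tests demonstrate correctness of the
machinery (matrix assembly, integration, steady states, GSA estimators) —
not that the power-law approximation is adequate for any particular real
pathway, that large stiff networks will settle within the default `t_max`,
or that the ε-floor is the right regularization for models that genuinely
reach zero concentration with negative orders (it is this package's choice;
other conventions — erroring, or shifting concentrations — are defensible).

## File formats

The TOML dialect and the plain-text BST dialect carry identical content
(species lists, reaction strings `name::A + 2*B --> C` with `[]` for an
empty side, kinetics strings `name::X^exp,…` with exponent defaulting to
1.0, overrides, and name→value tables for α, initial conditions, and static
values); both readers produce identical models from equivalent files, and
writers emit shortest-round-trip decimals so text round-trips are bit-exact.
The archive is a single JSON document with an explicit `schema_version`;
unknown versions are rejected with a versioned error. Numbers survive
save/load bit-exactly.

## Problem sizes used in the shipped checks

Peak-response simulation: 1001 output points over t ∈ [0, 50]. Sobol study:
base N = 1024 (9216 ODE solves), bootstrap 100. Morris: 500 trajectories
(4000 solves), 4 levels. Cross-oracle ensemble: 50 systems of 3–5 species.
Round-trip property: 100 random models per format.
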