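"""Reference pathway models and randomized generators for testing.

``feedback_pathway_model`` builds a five-species linear pathway with end
product feedback inhibition driven by a pulsed external input, and
``branched_pathway_model`` a five-species branch-point network with dual
feedback — the two worked examples this package's analyses are demonstrated
on.  ``random_model`` and ``random_classical_system`` generate seeded random
models for property and cross-oracle tests.
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    BSTModel,
    ClassicalSSystem,
    KineticsRecord,
    ReactionRecord,
    assemble_matrices,
)
from .sensitivity import ParameterMap, ParameterTarget
from .simulate import PulseSchedule

__all__ = [
    "feedback_pathway_model",
    "feedback_parameter_map",
    "branched_pathway_model",
    "random_model",
    "random_classical_system",
]


def feedback_pathway_model() -> tuple[BSTModel, PulseSchedule]:
    """Five-species linear pathway with end-product feedback inhibition.

    Precursor X1 is converted through X2 and X3 to the product X4, with a
    branch from X3 to the byproduct X5 (which has no degradation pathway).
    Static enzymes E1, E2, E3 (all 1.0) catalyze r1, r2, r3.  X4 feeds back
    on r1 with kinetic order -0.5, so product accumulation throttles entry
    into the pathway.  Production of X1 is driven not by a constant source
    (r0 carries rate constant 0) but by the returned pulse schedule:
    baseline u1 = 1 with a high pulse (u1 = 10) on t in [5, 15] and a medium
    pulse (u1 = 5) on t in [25, 35].

    Rate constants: r1 = r2 = r3 = 10, r4 = 3 (product degradation),
    r5 = 0.1 (branch), r0 = 0.  All initial conditions are 0.1 — strictly
    positive but small relative to the order-1..3 responses.
    """
    dynamic = ["X1", "X2", "X3", "X4", "X5"]
    static = ["E1", "E2", "E3"]
    reactions = [
        ReactionRecord("r0", reactants=[], products=[("X1", 1.0)]),
        ReactionRecord("r1", reactants=[("X1", 1.0)], products=[("X2", 1.0)]),
        ReactionRecord("r2", reactants=[("X2", 1.0)], products=[("X3", 1.0)]),
        ReactionRecord("r3", reactants=[("X3", 1.0)], products=[("X4", 1.0)]),
        ReactionRecord("r4", reactants=[("X4", 1.0)], products=[]),
        ReactionRecord("r5", reactants=[("X3", 1.0)], products=[("X5", 1.0)]),
    ]
    kinetics = [
        KineticsRecord("r1", [("X1", 1.0), ("E1", 1.0), ("X4", -0.5)]),
        KineticsRecord("r2", [("X2", 1.0), ("E2", 1.0)]),
        KineticsRecord("r3", [("X3", 1.0), ("E3", 1.0)]),
        KineticsRecord("r4", [("X4", 1.0)]),
        KineticsRecord("r5", [("X3", 1.0)]),
    ]
    S, G = assemble_matrices(dynamic, static, reactions, kinetics)
    alpha = {"r0": 0.0, "r1": 10.0, "r2": 10.0, "r3": 10.0, "r4": 3.0, "r5": 0.1}
    model = BSTModel(
        dynamic_species=dynamic,
        static_species=static,
        reaction_names=[r.name for r in reactions],
        S=S,
        G=G,
        alpha=np.array([alpha[r.name] for r in reactions]),
        x0=np.full(5, 0.1),
        xs=np.ones(3),
        metadata={"author": "bstkit", "version": "1.0",
                  "name": "feedback-inhibited linear pathway"},
    )
    schedule = PulseSchedule(
        baseline=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
        pulses=[[(5.0, 15.0, 10.0), (25.0, 35.0, 5.0)], [], [], [], []],
    )
    return model, schedule


def feedback_parameter_map() -> ParameterMap:
    """The seven-parameter sensitivity study for the feedback pathway.

    Six source/rate parameters at +/-50% of nominal plus the feedback
    kinetic order of X4 on r1 swept over [-2, 0].  Because X1 production is
    driven through the input schedule (the r0 rate constant is 0), the
    source parameter ``alpha_r0`` is the multiplicative scale on u1(t),
    nominal 1.0, bounds [0.5, 1.5].
    """
    targets = [
        ParameterTarget("input_scale", name="alpha_r0"),
        ParameterTarget("alpha", "r1", name="alpha_r1"),
        ParameterTarget("alpha", "r2", name="alpha_r2"),
        ParameterTarget("alpha", "r3", name="alpha_r3"),
        ParameterTarget("alpha", "r4", name="alpha_r4"),
        ParameterTarget("alpha", "r5", name="alpha_r5"),
        ParameterTarget("kinetic_order", ("X4", "r1"), name="g_X4_r1"),
    ]
    nominal = np.array([1.0, 10.0, 10.0, 10.0, 3.0, 0.1])
    lower = np.concatenate([0.5 * nominal, [-2.0]])
    upper = np.concatenate([1.5 * nominal, [0.0]])
    return ParameterMap(targets=targets, lower=lower, upper=upper)


def branched_pathway_model(
    alpha_defaults: float | dict[str, float] = 1.0,
    E3: float = 1.0,
    E4: float = 1.0,
) -> BSTModel:
    """Branch-point pathway with dual feedback inhibition.

    A constant source produces A, converted to B then to C, where the
    pathway branches: C -> D via r3 (catalyzed by E3) or C -> E via r4
    (catalyzed by E4); D and E are degraded first-order by r5 and r6.  Two
    feedback loops close the network: E inhibits r1 and D inhibits r2, each
    with kinetic order -0.5.  Rate constants default to 1.0 (they may be
    passed per reaction); the branch behavior studied with this fixture —
    flux redistribution as E3 is swept — is qualitative and does not depend
    on their exact values.
    """
    dynamic = ["A", "B", "C", "D", "E"]
    static = ["E3", "E4"]
    reactions = [
        ReactionRecord("r0", reactants=[], products=[("A", 1.0)]),
        ReactionRecord("r1", reactants=[("A", 1.0)], products=[("B", 1.0)]),
        ReactionRecord("r2", reactants=[("B", 1.0)], products=[("C", 1.0)]),
        ReactionRecord("r3", reactants=[("C", 1.0)], products=[("D", 1.0)]),
        ReactionRecord("r4", reactants=[("C", 1.0)], products=[("E", 1.0)]),
        ReactionRecord("r5", reactants=[("D", 1.0)], products=[]),
        ReactionRecord("r6", reactants=[("E", 1.0)], products=[]),
    ]
    kinetics = [
        KineticsRecord("r1", [("A", 1.0), ("E", -0.5)]),
        KineticsRecord("r2", [("B", 1.0), ("D", -0.5)]),
        KineticsRecord("r3", [("C", 1.0), ("E3", 1.0)]),
        KineticsRecord("r4", [("C", 1.0), ("E4", 1.0)]),
        KineticsRecord("r5", [("D", 1.0)]),
        KineticsRecord("r6", [("E", 1.0)]),
    ]
    S, G = assemble_matrices(dynamic, static, reactions, kinetics)
    names = [r.name for r in reactions]
    if isinstance(alpha_defaults, dict):
        alpha = np.array([float(alpha_defaults.get(n, 1.0)) for n in names])
    else:
        alpha = np.full(len(names), float(alpha_defaults))
    if np.any(alpha <= 0):
        raise ValueError("rate constants must be positive")
    return BSTModel(
        dynamic_species=dynamic,
        static_species=static,
        reaction_names=names,
        S=S,
        G=G,
        alpha=alpha,
        x0=np.full(5, 0.1),
        xs=np.array([float(E3), float(E4)]),
        metadata={"author": "bstkit", "version": "1.0",
                  "name": "branched pathway with dual feedback"},
    )


def random_model(n: int, m: int, p: int, seed: int | None = None) -> BSTModel:
    """Seeded random model with a connected reaction graph.

    Kinetic orders are drawn from [-1, 1], rate constants from [0.5, 5];
    intended for structural property tests (assembly, validation, file
    round-trips), not for dynamics.
    """
    if min(n, m, p) < 1:
        raise ValueError("need n, m, p >= 1")
    rng = np.random.default_rng(seed)
    dynamic = [f"X{i + 1}" for i in range(n)]
    static = [f"E{j + 1}" for j in range(m)]
    reactions = []
    kinetics = []
    for k in range(p):
        name = f"r{k}"
        # chain the first reactions through the species list so that every
        # dynamic species is touched and the graph is connected
        if k < n:
            src = dynamic[k - 1] if k > 0 else None
            dst = dynamic[k]
        else:
            src = dynamic[int(rng.integers(0, n))]
            dst = dynamic[int(rng.integers(0, n))] if rng.random() < 0.7 else None
        reactants = [(src, float(rng.integers(1, 3)))] if src else []
        products = [(dst, float(rng.integers(1, 3)))] if dst else []
        reactions.append(ReactionRecord(name, reactants=reactants, products=products))
        deps = []
        if src:
            deps.append((src, float(rng.uniform(-1, 1))))
        if rng.random() < 0.5:
            enzyme = static[int(rng.integers(0, m))]
            deps.append((enzyme, float(rng.uniform(-1, 1))))
        if deps:
            kinetics.append(KineticsRecord(name, deps))
    S, G = assemble_matrices(dynamic, static, reactions, kinetics)
    return BSTModel(
        dynamic_species=dynamic,
        static_species=static,
        reaction_names=[r.name for r in reactions],
        S=S,
        G=G,
        alpha=rng.uniform(0.5, 5.0, size=p),
        x0=rng.uniform(0.1, 2.0, size=n),
        xs=rng.uniform(0.5, 2.0, size=m),
        metadata={"author": "bstkit", "version": "1.0", "name": f"random-{seed}"},
    )


def random_classical_system(
    n: int, m: int = 0, seed: int | None = None
) -> ClassicalSSystem:
    """Seeded random classical S-system with a stable, well-conditioned
    steady state.

    Consumption is dominated by each species' own first-order-like term
    (``Hc`` diagonal in [0.6, 1.0]) with weak couplings elsewhere, so the
    dynamic block of ``Gc - Hc`` is strictly diagonally dominant: the
    log-linear system is well conditioned and forward integration settles.
    Orders stay within [-1, 1] and rate constants within [0.5, 5].
    """
    rng = np.random.default_rng(seed)
    off_scale = 0.3 / max(n - 1, 1)
    Gc = rng.uniform(-off_scale, off_scale, size=(n, n + m))
    Hc = rng.uniform(-off_scale, off_scale, size=(n, n + m))
    for i in range(n):
        Gc[i, i] = rng.uniform(-0.2, 0.2)
        Hc[i, i] = rng.uniform(0.6, 1.0)
    return ClassicalSSystem(
        alpha_c=rng.uniform(0.5, 5.0, size=n),
        beta_c=rng.uniform(0.5, 5.0, size=n),
        Gc=Gc,
        Hc=Hc,
        xs=rng.uniform(0.5, 2.0, size=m),
    )
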