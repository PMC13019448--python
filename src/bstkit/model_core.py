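"""Core domain types for Biochemical Systems Theory (S-system) models.

An S-system model describes a biochemical network with ``n`` dynamic species
and ``m`` static (externally fixed) species linked by ``p`` reactions.  The
network structure lives in the stoichiometric matrix ``S`` (n x p) and the
kinetics in the kinetic-order matrix ``G`` ((n+m) x p) together with the rate
constant vector ``alpha``.  Each reaction rate is a power law,
``r_k = alpha_k * prod_j X_j ** G[j, k]``, with the product running over the
concatenated vector of dynamic then static species.

Row ordering convention: rows of ``G`` are the dynamic species in model order
followed by the static species in model order.  This ordering is used
everywhere in the package (rates, file readers, parameter maps).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BSTModel",
    "ReactionRecord",
    "KineticsRecord",
    "ClassicalSSystem",
    "ModelValidationError",
    "assemble_matrices",
    "validate",
    "classical_from_model",
    "model_from_classical",
]


class ModelValidationError(ValueError):
    """Raised when declarative records or a model violate structural rules."""


@dataclass
class ReactionRecord:
    """Connectivity of one reaction: reactants and products with coefficients.

    Either side may be empty, describing a pure source (``[] --> X``) or sink
    (``X --> []``).  Coefficients are strictly positive; the stoichiometric
    sign convention (reactants negative, products positive) is applied during
    matrix assembly, not here.
    """

    name: str
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelValidationError("reaction name must be non-empty")
        for species, coeff in [*self.reactants, *self.products]:
            if coeff <= 0:
                raise ModelValidationError(
                    f"reaction {self.name!r}: coefficient for {species!r} "
                    f"must be > 0, got {coeff}"
                )


@dataclass
class KineticsRecord:
    """Rate-law dependencies of one reaction: (species, kinetic order) pairs.

    A positive exponent is activation, negative is inhibition.  Exponents are
    always explicit here; file readers supply the default of 1.0 for
    unannotated species.
    """

    reaction: str
    dependencies: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for species, exponent in self.dependencies:
            if not np.isfinite(exponent):
                raise ModelValidationError(
                    f"kinetics for {self.reaction!r}: exponent for "
                    f"{species!r} is not finite"
                )


@dataclass
class BSTModel:
    """Full state of an S-system model in generalized matrix form.

    Attributes
    ----------
    dynamic_species : list of str
        Names of the ``n`` time-evolving species, in state-vector order.
    static_species : list of str
        Names of the ``m`` externally fixed species (e.g. enzymes).
    reaction_names : list of str
        Names of the ``p`` reactions, in column order of ``S`` and ``G``.
    S : ndarray, shape (n, p)
        Stoichiometric matrix (reactants negative, products positive).
    G : ndarray, shape (n + m, p)
        Kinetic-order matrix; rows are dynamic species then static species.
    alpha : ndarray, shape (p,)
        Non-negative rate constants.
    x0 : ndarray, shape (n,)
        Initial concentrations (non-negative).
    xs : ndarray, shape (m,)
        Static species concentrations (strictly positive).

    The object is mutable: parameters, initial conditions and matrix entries
    may be adjusted in place after construction.
    """

    dynamic_species: list[str]
    static_species: list[str]
    reaction_names: list[str]
    S: np.ndarray
    G: np.ndarray
    alpha: np.ndarray
    x0: np.ndarray
    xs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.x0 = np.asarray(self.x0, dtype=float).ravel()
        self.xs = np.asarray(self.xs, dtype=float).ravel()

    # -- dimensions ---------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of dynamic species."""
        return len(self.dynamic_species)

    @property
    def m(self) -> int:
        """Number of static species."""
        return len(self.static_species)

    @property
    def p(self) -> int:
        """Number of reactions."""
        return len(self.reaction_names)

    @property
    def species(self) -> list[str]:
        """All species names, dynamic first then static (the G row order)."""
        return [*self.dynamic_species, *self.static_species]

    def species_index(self, name: str) -> int:
        """Row index of *name* in the concatenated (dynamic, static) order."""
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def reaction_index(self, name: str) -> int:
        try:
            return self.reaction_names.index(name)
        except ValueError:
            raise KeyError(f"unknown reaction {name!r}") from None

    def copy(self) -> "BSTModel":
        """Deep copy (parameter perturbations never share state)."""
        return copy.deepcopy(self)


@dataclass
class ClassicalSSystem:
    """Classical two-term S-system: one aggregate production and one
    aggregate consumption power law per dynamic species.

    ``dx_i/dt = alpha_c[i] * prod_j X_j**Gc[i, j] - beta_c[i] * prod_j X_j**Hc[i, j]``

    with the product over dynamic then static species.  ``alpha_c`` and
    ``beta_c`` must be strictly positive so the steady state admits the
    log-linear transformation.
    """

    alpha_c: np.ndarray  # (n,)
    beta_c: np.ndarray  # (n,)
    Gc: np.ndarray  # (n, n + m)
    Hc: np.ndarray  # (n, n + m)
    xs: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        self.alpha_c = np.asarray(self.alpha_c, dtype=float).ravel()
        self.beta_c = np.asarray(self.beta_c, dtype=float).ravel()
        self.Gc = np.atleast_2d(np.asarray(self.Gc, dtype=float))
        self.Hc = np.atleast_2d(np.asarray(self.Hc, dtype=float))
        self.xs = np.asarray(self.xs, dtype=float).ravel()
        n = self.alpha_c.size
        if self.beta_c.size != n or self.Gc.shape != (n, n + self.xs.size):
            raise ModelValidationError("classical S-system dimensions inconsistent")
        if self.Hc.shape != self.Gc.shape:
            raise ModelValidationError("Gc and Hc shapes differ")
        if np.any(self.alpha_c <= 0) or np.any(self.beta_c <= 0):
            raise ModelValidationError("classical rate constants must be > 0")

    @property
    def n(self) -> int:
        return self.alpha_c.size

    @property
    def m(self) -> int:
        return self.xs.size


def assemble_matrices(
    dynamic_names: list[str],
    static_names: list[str],
    reactions: list[ReactionRecord],
    kinetics: list[KineticsRecord],
    overrides: list[tuple[str, str, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Compile declarative records into the matrices ``S`` and ``G``.

    ``S[i, k]`` is the net stoichiometric change of dynamic species ``i`` in
    reaction ``k`` (product coefficients minus reactant coefficients), after
    which *overrides* — ``(species, reaction, coefficient)`` triples —
    replace the computed entry verbatim (a zero override lets a species
    catalyze a reaction without mass flow).  ``G[j, k]`` holds the kinetic
    order of species ``j`` in reaction ``k`` from the kinetics records, 0
    where absent.  Static species contribute rows of ``G`` but not ``S``.

    Raises
    ------
    ModelValidationError
        On unknown species/reaction names or duplicate exponent entries.
    """
    overrides = overrides or []
    n, m = len(dynamic_names), len(static_names)
    dyn_index = {name: i for i, name in enumerate(dynamic_names)}
    all_index = {name: i for i, name in enumerate([*dynamic_names, *static_names])}
    rxn_index = {r.name: k for k, r in enumerate(reactions)}
    if len(rxn_index) != len(reactions):
        raise ModelValidationError("duplicate reaction names")
    p = len(reactions)

    S = np.zeros((n, p))
    for k, rec in enumerate(reactions):
        for species, coeff in rec.reactants:
            if species not in all_index:
                raise ModelValidationError(
                    f"reaction {rec.name!r}: unknown species {species!r}"
                )
            if species in dyn_index:
                S[dyn_index[species], k] -= coeff
        for species, coeff in rec.products:
            if species not in all_index:
                raise ModelValidationError(
                    f"reaction {rec.name!r}: unknown species {species!r}"
                )
            if species in dyn_index:
                S[dyn_index[species], k] += coeff

    for species, reaction, coeff in overrides:
        if species not in dyn_index:
            raise ModelValidationError(
                f"stoichiometry override: unknown dynamic species {species!r}"
            )
        if reaction not in rxn_index:
            raise ModelValidationError(
                f"stoichiometry override: unknown reaction {reaction!r}"
            )
        S[dyn_index[species], rxn_index[reaction]] = coeff

    G = np.zeros((n + m, p))
    seen: set[tuple[str, str]] = set()
    for rec in kinetics:
        if rec.reaction not in rxn_index:
            raise ModelValidationError(
                f"kinetics record: unknown reaction {rec.reaction!r}"
            )
        k = rxn_index[rec.reaction]
        for species, exponent in rec.dependencies:
            if species not in all_index:
                raise ModelValidationError(
                    f"kinetics for {rec.reaction!r}: unknown species {species!r}"
                )
            key = (species, rec.reaction)
            if key in seen:
                raise ModelValidationError(
                    f"duplicate kinetic order for species {species!r} "
                    f"in reaction {rec.reaction!r}"
                )
            seen.add(key)
            G[all_index[species], k] = exponent
    return S, G


def validate(model: BSTModel) -> list[str]:
    """Check all BSTModel invariants; return diagnostics (empty = valid).

    Diagnostics are strings naming the violated invariant and its location.
    No exception is raised; callers that need hard failure promote the list
    themselves (as :func:`bstkit.io_formats.build` does).
    """
    diags: list[str] = []
    n, m, p = model.n, model.m, model.p

    if len(set(model.dynamic_species)) != n:
        diags.append("duplicate names in dynamic_species")
    if len(set(model.static_species)) != m:
        diags.append("duplicate names in static_species")
    if set(model.dynamic_species) & set(model.static_species):
        overlap = sorted(set(model.dynamic_species) & set(model.static_species))
        diags.append(f"species both dynamic and static: {overlap}")
    if len(set(model.reaction_names)) != p:
        diags.append("duplicate reaction names")

    if model.S.shape != (n, p):
        diags.append(f"S has shape {model.S.shape}, expected {(n, p)}")
    if model.G.shape != (n + m, p):
        diags.append(f"G has shape {model.G.shape}, expected {(n + m, p)}")
    if model.alpha.shape != (p,):
        diags.append(f"alpha has length {model.alpha.size}, expected {p}")
    if model.x0.shape != (n,):
        diags.append(f"x0 has length {model.x0.size}, expected {n}")
    if model.xs.shape != (m,):
        diags.append(f"xs has length {model.xs.size}, expected {m}")

    for arr, name in [(model.S, "S"), (model.G, "G")]:
        if not np.all(np.isfinite(arr)):
            diags.append(f"{name} contains non-finite entries")
    for i in np.flatnonzero(~(model.alpha >= 0)):
        diags.append(f"negative rate constant at index {i} ({model.alpha[i]})")
    for i in np.flatnonzero(~(model.x0 >= 0)):
        diags.append(f"negative initial condition at index {i} ({model.x0[i]})")
    for i in np.flatnonzero(~(model.xs > 0)):
        diags.append(f"non-positive static value at index {i} ({model.xs[i]})")
    return diags


def classical_from_model(model: BSTModel) -> ClassicalSSystem:
    """Aggregate a generalized model into the classical two-term form.

    Representable subclass only: each dynamic species may have at most one
    producing reaction (S entry +1) and at most one consuming reaction
    (S entry -1), and both rate constants must be strictly positive.  The
    classical exponent rows ``Gc[i]`` / ``Hc[i]`` are the kinetic-order
    columns of the producing / consuming reactions.

    Raises
    ------
    ModelValidationError
        If some species has multiple producers/consumers, a stoichiometric
        coefficient with magnitude other than 1, or a zero rate constant.
    """
    n, m = model.n, model.m
    alpha_c = np.zeros(n)
    beta_c = np.zeros(n)
    Gc = np.zeros((n, n + m))
    Hc = np.zeros((n, n + m))
    for i, name in enumerate(model.dynamic_species):
        row = model.S[i]
        producers = np.flatnonzero(row > 0)
        consumers = np.flatnonzero(row < 0)
        if len(producers) != 1 or len(consumers) != 1:
            raise ModelValidationError(
                f"not classically representable: species {name!r} has "
                f"{len(producers)} producing and {len(consumers)} consuming "
                "reactions (need exactly one of each)"
            )
        kp, kc = producers[0], consumers[0]
        if row[kp] != 1 or row[kc] != -1:
            raise ModelValidationError(
                f"not classically representable: species {name!r} has "
                f"stoichiometric coefficients {row[kp]}, {row[kc]} (need +1/-1)"
            )
        if model.alpha[kp] <= 0 or model.alpha[kc] <= 0:
            raise ModelValidationError(
                f"not classically representable: species {name!r} has a "
                "zero rate constant on its production or consumption term"
            )
        alpha_c[i] = model.alpha[kp]
        beta_c[i] = model.alpha[kc]
        Gc[i] = model.G[:, kp]
        Hc[i] = model.G[:, kc]
    return ClassicalSSystem(alpha_c, beta_c, Gc, Hc, model.xs.copy())


def model_from_classical(
    cs: ClassicalSSystem,
    dynamic_species: list[str] | None = None,
    static_species: list[str] | None = None,
    x0: np.ndarray | None = None,
) -> BSTModel:
    """Expand a classical S-system into the generalized matrix form.

    Species ``i`` gets a producing reaction ``prod_i`` (rate constant
    ``alpha_c[i]``, exponents ``Gc[i]``) and a consuming reaction ``cons_i``
    (``beta_c[i]``, ``Hc[i]``); :func:`classical_from_model` is its inverse
    on this subclass.
    """
    n, m = cs.n, cs.m
    dynamic_species = dynamic_species or [f"X{i + 1}" for i in range(n)]
    static_species = static_species or [f"Z{j + 1}" for j in range(m)]
    reaction_names = [f"prod_{s}" for s in dynamic_species] + [
        f"cons_{s}" for s in dynamic_species
    ]
    S = np.hstack([np.eye(n), -np.eye(n)])
    G = np.hstack([cs.Gc.T, cs.Hc.T])  # (n+m, 2n)
    alpha = np.concatenate([cs.alpha_c, cs.beta_c])
    x0 = np.ones(n) if x0 is None else np.asarray(x0, dtype=float)
    return BSTModel(
        dynamic_species=dynamic_species,
        static_species=static_species,
        reaction_names=reaction_names,
        S=S,
        G=G,
        alpha=alpha,
        x0=x0,
        xs=cs.xs.copy(),
    )
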