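"""Global sensitivity analysis: Morris screening and Sobol indices.

Both methods treat the model as a black-box map from a parameter vector to a
scalar output (here typically the time-integrated concentration of a product
species).  The Morris method estimates elementary effects — normalized
finite differences along one-at-a-time trajectories through the parameter
hypercube — and summarizes each parameter by the mean ``mu``, mean absolute
value ``mu_star`` and variance ``sigma2`` of its effects.  Large ``mu_star``
flags an influential parameter; large ``sigma2`` flags nonlinearity or
interaction.  The Sobol method decomposes the output variance into
first-order (``S1``) and total-order (``ST``) contributions using a
Saltelli-style design over a scrambled low-discrepancy sequence, with the
Saltelli-2010 estimator for ``S1`` and the Jansen estimator for ``ST``;
confidence intervals come from a row bootstrap.

Parameter perturbations go through :class:`ParameterMap`, which rebinds
selected model quantities (rate constants, kinetic orders, static values,
initial conditions, or the external-input scale) on a deep copy per
evaluation, so objective evaluations are pure and independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .model_core import BSTModel
from .simulate import IntegrationError, PulseSchedule, evaluate

__all__ = [
    "ParameterTarget",
    "ParameterMap",
    "MorrisResult",
    "SobolResult",
    "performance_integral",
    "make_objective",
    "morris",
    "sobol",
]


class EvaluationError(RuntimeError):
    """Too many objective evaluations failed during a sensitivity run."""


# ---------------------------------------------------------------------------
# parameter mapping
# ---------------------------------------------------------------------------

@dataclass
class ParameterTarget:
    """One tunable quantity in a sensitivity study.

    ``kind`` is one of:

    * ``"alpha"`` — a rate constant; ``ref`` is the reaction name or index.
    * ``"kinetic_order"`` — a ``G`` entry; ``ref`` is ``(species, reaction)``.
    * ``"static_value"`` — a static concentration; ``ref`` is the species.
    * ``"initial"`` — an initial condition; ``ref`` is the dynamic species.
    * ``"input_scale"`` — multiplicative scale on the external input
      schedule; ``ref`` is ignored.  This expresses a source amplitude as a
      parameter when production is driven through ``u(t)`` rather than a
      rate constant.
    """

    kind: str
    ref: object = None
    name: str = ""

    def __post_init__(self) -> None:
        kinds = {"alpha", "kinetic_order", "static_value", "initial", "input_scale"}
        if self.kind not in kinds:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if not self.name:
            if self.kind == "input_scale":
                self.name = "input_scale"
            elif self.kind == "kinetic_order":
                self.name = f"g_{self.ref[0]}_{self.ref[1]}"
            else:
                self.name = f"{self.kind}_{self.ref}"


@dataclass
class ParameterMap:
    """Ordered parameter targets with box bounds, bound to a model."""

    targets: list[ParameterTarget]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float).ravel()
        self.upper = np.asarray(self.upper, dtype=float).ravel()
        d = len(self.targets)
        if self.lower.size != d or self.upper.size != d:
            raise ValueError("bounds length must match number of targets")
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ValueError("bounds must be finite")
        if np.any(self.lower >= self.upper):
            bad = int(np.flatnonzero(self.lower >= self.upper)[0])
            raise ValueError(
                f"lower bound >= upper bound for parameter "
                f"{self.targets[bad].name!r}"
            )

    @property
    def d(self) -> int:
        return len(self.targets)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.targets]

    @property
    def bounds(self) -> np.ndarray:
        return np.column_stack([self.lower, self.upper])

    def check(self, model: BSTModel) -> None:
        """Raise KeyError if any target does not resolve in *model*."""
        for t in self.targets:
            if t.kind == "alpha":
                if isinstance(t.ref, str):
                    model.reaction_index(t.ref)
            elif t.kind == "kinetic_order":
                species, reaction = t.ref
                model.species_index(species)
                model.reaction_index(reaction)
            elif t.kind == "static_value":
                if t.ref not in model.static_species:
                    raise KeyError(f"unknown static species {t.ref!r}")
            elif t.kind == "initial":
                if t.ref not in model.dynamic_species:
                    raise KeyError(f"unknown dynamic species {t.ref!r}")

    def apply(
        self,
        model: BSTModel,
        input: PulseSchedule | None,
        theta: np.ndarray,
    ) -> tuple[BSTModel, PulseSchedule | None]:
        """Return deep copies of (model, input) with *theta* substituted in."""
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != self.d:
            raise ValueError(f"theta has length {theta.size}, expected {self.d}")
        m = model.copy()
        inp = (
            PulseSchedule(
                baseline=input.baseline.copy(),
                pulses=[list(ch) for ch in input.pulses],
                scale=input.scale,
            )
            if input is not None
            else None
        )
        for value, t in zip(theta, self.targets):
            if t.kind == "alpha":
                k = m.reaction_index(t.ref) if isinstance(t.ref, str) else int(t.ref)
                m.alpha[k] = value
            elif t.kind == "kinetic_order":
                species, reaction = t.ref
                m.G[m.species_index(species), m.reaction_index(reaction)] = value
            elif t.kind == "static_value":
                m.xs[m.static_species.index(t.ref)] = value
            elif t.kind == "initial":
                m.x0[m.dynamic_species.index(t.ref)] = value
            else:  # input_scale
                if inp is None:
                    raise ValueError("input_scale parameter requires an input schedule")
                inp.scale = value
        return m, inp


# ---------------------------------------------------------------------------
# performance functional
# ---------------------------------------------------------------------------

def performance_integral(
    model: BSTModel,
    tspan: tuple[float, float],
    input: PulseSchedule | None,
    species: str,
    t_upper: float,
    n_points: int = 2001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Trapezoidal integral of one species' trajectory from t0 to *t_upper*.

    The trajectory is sampled on a dense uniform grid (default 2001 points)
    over ``[t0, t_upper]``; *t_upper* must lie within *tspan*.
    """
    t0, tf = float(tspan[0]), float(tspan[1])
    if not (t0 < t_upper <= tf):
        raise ValueError(f"t_upper={t_upper} must lie in ({t0}, {tf}]")
    if species not in model.dynamic_species:
        raise KeyError(f"unknown species {species!r}")
    grid = np.linspace(t0, t_upper, max(int(n_points), 2001))
    traj = evaluate(
        model, (t0, t_upper), input=input, save_times=grid, rtol=rtol, atol=atol
    )
    return float(np.trapezoid(traj.column(species), traj.times))


def make_objective(
    model: BSTModel,
    pmap: ParameterMap,
    input: PulseSchedule | None = None,
    tspan: tuple[float, float] = (0.0, 20.0),
    species: str | None = None,
    t_upper: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
):
    """Build the scalar objective ``theta -> J`` used by morris/sobol.

    ``J`` is the time integral of *species* over ``[t0, t_upper]``.  The
    returned callable carries a ``retry`` attribute that re-evaluates with
    tenfold tighter tolerances; the sensitivity drivers invoke it when an
    evaluation fails before recording the point as missing.
    """
    pmap.check(model)
    species = species or model.dynamic_species[-1]
    t_upper = tspan[1] if t_upper is None else t_upper

    def _eval(theta, rtol_, atol_):
        m, inp = pmap.apply(model, input, theta)
        return performance_integral(
            m, tspan, inp, species, t_upper, rtol=rtol_, atol=atol_
        )

    def f(theta):
        return _eval(theta, rtol, atol)

    f.retry = lambda theta: _eval(theta, rtol / 10.0, atol / 10.0)
    f.parameter_names = pmap.names
    return f


def _safe_eval(f, theta) -> float:
    """Evaluate with one tighter-tolerance retry; NaN marks a missing point."""
    try:
        y = f(theta)
        if np.isfinite(y):
            return float(y)
    except (IntegrationError, FloatingPointError, ValueError):
        pass
    retry = getattr(f, "retry", None)
    if retry is not None:
        try:
            y = retry(theta)
            if np.isfinite(y):
                return float(y)
        except (IntegrationError, FloatingPointError, ValueError):
            pass
    return float("nan")


# ---------------------------------------------------------------------------
# Morris elementary-effects screening
# ---------------------------------------------------------------------------

@dataclass
class MorrisResult:
    """Per-parameter elementary-effect summaries from a Morris screen.

    ``mu`` is the signed mean effect, ``mu_star`` the mean absolute effect
    (the standard screening/ranking statistic), and ``sigma2`` the sample
    variance of the effects (nonlinearity/interaction indicator).
    """

    names: list[str]
    mu: np.ndarray
    mu_star: np.ndarray
    sigma2: np.ndarray
    n_trajectories: int
    n_missing: int
    seed: int | None

    def ranking(self) -> list[str]:
        """Parameter names sorted by decreasing ``mu_star``."""
        order = np.argsort(-self.mu_star)
        return [self.names[i] for i in order]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parameter,mu,mu_star,sigma2\n")
            for i, name in enumerate(self.names):
                fh.write(
                    f"{name},{self.mu[i]!r},{self.mu_star[i]!r},{self.sigma2[i]!r}\n"
                )

    def to_json(self, path=None):
        payload = {
            "method": "morris",
            "n_trajectories": self.n_trajectories,
            "n_missing": self.n_missing,
            "seed": self.seed,
            "parameters": {
                name: {
                    "mu": self.mu[i],
                    "mu_star": self.mu_star[i],
                    "sigma2": self.sigma2[i],
                }
                for i, name in enumerate(self.names)
            },
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload


def morris(
    f,
    bounds: np.ndarray,
    trajectories: int = 500,
    levels: int = 4,
    seed: int | None = None,
    names: list[str] | None = None,
) -> MorrisResult:
    """Morris one-at-a-time elementary-effects screening.

    Parameters
    ----------
    f : callable
        Scalar objective on the original (bounded) parameter scale.
    bounds : array-like, shape (d, 2)
        Lower/upper bound per parameter.
    trajectories : int
        Number of random trajectories ``r``; each costs ``d + 1``
        evaluations and yields one elementary effect per parameter.
    levels : int
        Even number of grid levels ``p``; the step is
        ``delta = p / (2 (p - 1))`` in unit-hypercube coordinates.
    seed : int, optional
        Seeds the trajectory design; fixed seed gives bit-identical results.

    Elementary effects are computed in unit-hypercube coordinates,
    ``EE_k = (f(theta + delta * e_k * span) - f(theta)) / delta`` with the
    sign referred to increasing parameter value.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    d = bounds.shape[0]
    lower, upper = bounds[:, 0], bounds[:, 1]
    span = upper - lower
    if trajectories < 2:
        raise ValueError("need at least 2 trajectories")
    if levels < 2 or levels % 2:
        raise ValueError("levels must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))

    effects = np.full((trajectories, d), np.nan)
    for t in range(trajectories):
        # base point on the sub-grid from which a +delta step stays inside
        base = rng.integers(0, levels // 2, size=d) / (levels - 1.0)
        direction = rng.choice([-1.0, 1.0], size=d)
        x = base + np.where(direction < 0, delta, 0.0)
        order = rng.permutation(d)
        y_prev = _safe_eval(f, lower + x * span)
        for k in order:
            x = x.copy()
            x[k] += direction[k] * delta
            y_next = _safe_eval(f, lower + x * span)
            if not (np.isnan(y_prev) or np.isnan(y_next)):
                effects[t, k] = (y_next - y_prev) / (direction[k] * delta)
            y_prev = y_next
    n_missing = int(np.isnan(effects).sum())
    if n_missing > 0.01 * effects.size:
        raise EvaluationError(
            f"{n_missing} of {effects.size} elementary effects missing (>1%)"
        )
    mu = np.nanmean(effects, axis=0)
    mu_star = np.nanmean(np.abs(effects), axis=0)
    sigma2 = np.nanvar(effects, axis=0, ddof=1)
    return MorrisResult(
        names=list(names) if names else [f"theta_{i}" for i in range(d)],
        mu=mu,
        mu_star=mu_star,
        sigma2=sigma2,
        n_trajectories=trajectories,
        n_missing=n_missing,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Sobol variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class SobolResult:
    """First- and total-order Sobol indices with bootstrap 95% CIs."""

    names: list[str]
    S1: np.ndarray
    ST: np.ndarray
    S1_ci: np.ndarray  # (d, 2)
    ST_ci: np.ndarray  # (d, 2)
    n_base: int
    n_missing: int
    seed: int | None
    degenerate: bool = False  # True when the output variance was zero

    def ranking(self) -> list[str]:
        """Parameter names sorted by decreasing total-order index."""
        order = np.argsort(-self.ST)
        return [self.names[i] for i in order]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parameter,S1,S1_lo,S1_hi,ST,ST_lo,ST_hi\n")
            for i, name in enumerate(self.names):
                fh.write(
                    f"{name},{self.S1[i]!r},{self.S1_ci[i, 0]!r},"
                    f"{self.S1_ci[i, 1]!r},{self.ST[i]!r},"
                    f"{self.ST_ci[i, 0]!r},{self.ST_ci[i, 1]!r}\n"
                )

    def to_json(self, path=None):
        payload = {
            "method": "sobol",
            "n_base": self.n_base,
            "n_missing": self.n_missing,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "parameters": {
                name: {
                    "S1": self.S1[i],
                    "S1_ci": self.S1_ci[i].tolist(),
                    "ST": self.ST[i],
                    "ST_ci": self.ST_ci[i].tolist(),
                }
                for i, name in enumerate(self.names)
            },
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload


def _sobol_estimators(fA, fB, fAB):
    """Saltelli-2010 S1 and Jansen ST from the three evaluation blocks."""
    V = np.var(np.concatenate([fA, fB]), ddof=1)
    if V <= 0:
        return np.zeros(fAB.shape[1]), np.zeros(fAB.shape[1]), V
    S1 = np.mean(fB[:, None] * (fAB - fA[:, None]), axis=0) / V
    ST = 0.5 * np.mean((fA[:, None] - fAB) ** 2, axis=0) / V
    return S1, ST, V


def sobol(
    f,
    bounds: np.ndarray,
    base_samples: int = 1024,
    seed: int | None = None,
    bootstrap: int = 200,
    names: list[str] | None = None,
) -> SobolResult:
    """Sobol variance-based sensitivity indices via a Saltelli design.

    Two base matrices ``A`` and ``B`` (``N x d``) are drawn from a scrambled
    low-discrepancy sequence, plus ``d`` cross matrices ``A_B^(i)`` equal to
    ``A`` with column ``i`` taken from ``B`` — ``N (d + 2)`` model
    evaluations in total.  First-order indices use the Saltelli-2010
    estimator, total-order indices the Jansen estimator.  95% confidence
    intervals come from bootstrapping the sample rows (*bootstrap*
    resamples; no additional model evaluations).

    With a zero-variance output the indices are all reported 0 and the
    ``degenerate`` flag is set.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    d = bounds.shape[0]
    lower, span = bounds[:, 0], bounds[:, 1] - bounds[:, 0]
    N = int(base_samples)
    if N < 64:
        raise ValueError("base_samples must be >= 64")
    ss = np.random.SeedSequence(seed)
    qmc_seed, boot_seed = ss.spawn(2)
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=np.random.default_rng(qmc_seed))
    M = sampler.random(N)
    A = lower + M[:, :d] * span
    B = lower + M[:, d:] * span

    fA = np.array([_safe_eval(f, row) for row in A])
    fB = np.array([_safe_eval(f, row) for row in B])
    fAB = np.empty((N, d))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[:, i] = [_safe_eval(f, row) for row in ABi]

    missing_mask = np.isnan(fA) | np.isnan(fB) | np.isnan(fAB).any(axis=1)
    n_missing = int(np.isnan(fA).sum() + np.isnan(fB).sum() + np.isnan(fAB).sum())
    total_evals = N * (d + 2)
    if n_missing > 0.01 * total_evals:
        raise EvaluationError(
            f"{n_missing} of {total_evals} objective evaluations failed (>1%)"
        )
    keep = ~missing_mask
    fA, fB, fAB = fA[keep], fB[keep], fAB[keep]
    n_keep = fA.size

    S1, ST, V = _sobol_estimators(fA, fB, fAB)
    degenerate = V <= 0

    rng = np.random.default_rng(boot_seed)
    if degenerate or bootstrap < 2:
        S1_ci = np.column_stack([S1, S1])
        ST_ci = np.column_stack([ST, ST])
    else:
        S1_bs = np.empty((bootstrap, d))
        ST_bs = np.empty((bootstrap, d))
        for b in range(bootstrap):
            idx = rng.integers(0, n_keep, size=n_keep)
            S1_bs[b], ST_bs[b], _ = _sobol_estimators(fA[idx], fB[idx], fAB[idx])
        S1_ci = np.percentile(S1_bs, [2.5, 97.5], axis=0).T
        ST_ci = np.percentile(ST_bs, [2.5, 97.5], axis=0).T

    return SobolResult(
        names=list(names) if names else [f"theta_{i}" for i in range(d)],
        S1=S1,
        ST=ST,
        S1_ci=S1_ci,
        ST_ci=ST_ci,
        n_base=N,
        n_missing=n_missing,
        seed=seed,
        degenerate=bool(degenerate),
    )
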