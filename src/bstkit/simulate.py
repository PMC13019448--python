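"""Power-law rate evaluation, ODE integration, and steady-state solvers.

The dynamics follow ``dx/dt = S @ r(x, xs) + u(t)`` with power-law rates
``r_k = alpha_k * prod_j X_j ** G[j, k]`` over the concatenated species
vector.  Concentrations are floored at ``EPS_CONC`` inside the rate law only,
so negative kinetic orders (feedback inhibition) remain finite when a species
starts at or transiently crosses zero; the integrated state itself is never
clamped.

Steady states can be computed two ways: dynamic settling (forward
integration until the derivatives vanish to tolerance), which works for any
model, and the log-linear solve, which applies only to the classical two-term
form but is exact up to linear-algebra round-off.  The two serve as mutual
cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import BSTModel, ClassicalSSystem

__all__ = [
    "PulseSchedule",
    "Trajectory",
    "SteadyStateResult",
    "IntegrationError",
    "SteadyStateError",
    "rates",
    "rhs",
    "evaluate",
    "steadystate",
    "solve_loglinear",
]

#: Floor applied to concentrations inside the rate law (not to the state).
EPS_CONC = 1e-8

#: Default integrator tolerances.
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last successful time."""

    def __init__(self, message: str, t_last: float | None = None):
        super().__init__(message)
        self.t_last = t_last


class SteadyStateError(RuntimeError):
    """Dynamic settling did not converge; carries the last state/residual."""

    def __init__(self, message: str, x_last: np.ndarray, residual: float):
        super().__init__(message)
        self.x_last = x_last
        self.residual = residual


@dataclass
class PulseSchedule:
    """Piecewise-constant external input ``u(t)`` for the dynamic species.

    Each channel ``i`` (one per dynamic species) holds ``baseline[i]``
    except during its pulses, where ``u_i(t)`` equals the pulse amplitude
    (the amplitude replaces, not adds to, the baseline).  Pulses within a
    channel must not overlap.  ``scale`` multiplies the whole schedule and
    is the hook used by sensitivity analysis to treat the source amplitude
    as a parameter.
    """

    baseline: np.ndarray
    pulses: list[list[tuple[float, float, float]]] = field(default_factory=list)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.baseline = np.atleast_1d(np.asarray(self.baseline, dtype=float))
        if not self.pulses:
            self.pulses = [[] for _ in range(self.baseline.size)]
        if len(self.pulses) != self.baseline.size:
            raise ValueError(
                f"{len(self.pulses)} pulse channels for "
                f"{self.baseline.size} baseline entries"
            )
        for ch, plist in enumerate(self.pulses):
            plist.sort(key=lambda pulse: pulse[0])
            prev_stop = -np.inf
            for start, stop, _amp in plist:
                if start >= stop:
                    raise ValueError(
                        f"channel {ch}: pulse start {start} must precede stop {stop}"
                    )
                if start < prev_stop:
                    raise ValueError(f"channel {ch}: overlapping pulses")
                prev_stop = stop

    @property
    def n_channels(self) -> int:
        return self.baseline.size

    def value(self, t: float) -> np.ndarray:
        """Input vector u(t)."""
        u = self.baseline.copy()
        for ch, plist in enumerate(self.pulses):
            for start, stop, amp in plist:
                if start <= t < stop:
                    u[ch] = amp
                    break
        return u * self.scale

    def breakpoints(self, t0: float, tf: float) -> np.ndarray:
        """Sorted pulse edges strictly inside (t0, tf)."""
        edges = {
            t
            for plist in self.pulses
            for start, stop, _ in plist
            for t in (start, stop)
            if t0 < t < tf
        }
        return np.array(sorted(edges))


@dataclass
class Trajectory:
    """Simulation output: time points and the state matrix.

    ``states[i, j]`` is the concentration of dynamic species ``j`` at
    ``times[i]``.
    """

    times: np.ndarray
    states: np.ndarray
    species: list[str]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.states[:, self.species.index(name)]
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def to_csv(self, path) -> None:
        header = ",".join(["time", *self.species])
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter=",", header=header, comments="")


@dataclass
class SteadyStateResult:
    """Steady state with the residual ``||S r + u||_inf`` achieved."""

    x: np.ndarray
    residual: float
    t_settle: float


def rates(x: np.ndarray, model: BSTModel) -> np.ndarray:
    """Power-law reaction rates at state ``x``.

    Computed as ``alpha * exp(G.T @ log(max(X, eps)))`` over the concatenated
    (dynamic, static) species vector.  Zero exponents contribute a factor of
    exactly 1 even at zero concentration.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite concentrations passed to rates()")
    X = np.concatenate([x, model.xs])
    logX = np.log(np.maximum(X, EPS_CONC))
    return model.alpha * np.exp(model.G.T @ logX)


def rhs(
    t: float,
    x: np.ndarray,
    model: BSTModel,
    input: PulseSchedule | None = None,
) -> np.ndarray:
    """Time derivative ``S @ r(x) + u(t)`` of the dynamic state."""
    dx = model.S @ rates(x, model)
    if input is not None:
        if input.n_channels != model.n:
            raise ValueError(
                f"input has {input.n_channels} channels, model has {model.n} species"
            )
        dx = dx + input.value(t)
    return dx


def _make_rhs(model: BSTModel, u: np.ndarray | None):
    """Closure with hoisted arrays; u is the constant input on one segment."""
    GT = np.ascontiguousarray(model.G.T)
    S = model.S
    alpha = model.alpha
    xs = model.xs
    n = model.n

    def f(t, x):
        X = np.empty(n + xs.size)
        X[:n] = x
        X[n:] = xs
        np.maximum(X, EPS_CONC, out=X)
        dx = S @ (alpha * np.exp(GT @ np.log(X)))
        if u is not None:
            dx = dx + u
        return dx

    return f


def evaluate(
    model: BSTModel,
    tspan: tuple[float, float] = (0.0, 10.0),
    input: PulseSchedule | None = None,
    save_times: np.ndarray | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``tspan``, sampling at ``save_times``.

    The input schedule is piecewise constant, so integration is segmented at
    every pulse edge and the integrator restarted there; an adaptive stepper
    crossing a x10 step input unsegmented loses accuracy.  Default sampling
    is 1001 uniform points.  The stiff-capable LSODA method is used by
    default, with an automatic fallback to Radau on failure.
    """
    t0, tf = float(tspan[0]), float(tspan[1])
    if not t0 < tf:
        raise ValueError(f"tspan must satisfy t0 < tf, got {tspan}")
    if input is not None and input.n_channels != model.n:
        raise ValueError(
            f"input has {input.n_channels} channels, model has {model.n} species"
        )
    if save_times is None:
        save_times = np.linspace(t0, tf, 1001)
    else:
        save_times = np.asarray(save_times, dtype=float)
        if save_times[0] < t0 or save_times[-1] > tf:
            raise ValueError("save_times must lie within tspan")

    edges = input.breakpoints(t0, tf) if input is not None else np.array([])
    seg_bounds = np.concatenate([[t0], edges, [tf]])

    states = np.empty((save_times.size, model.n))
    x = model.x0.copy()
    filled = 0
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        u = input.value(0.5 * (a + b)) if input is not None else None
        f = _make_rhs(model, u)
        # save points in [a, b); the final segment also takes t == tf
        hi = int(np.searchsorted(save_times, b, side="right" if b == tf else "left"))
        seg_saves = save_times[filled:hi]
        # always integrate exactly to b so the next segment starts there
        if seg_saves.size and seg_saves[-1] == b:
            t_eval = seg_saves
        else:
            t_eval = np.append(seg_saves, b)
        sol = solve_ivp(
            f, (a, b), x, method=method, t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success and method == "LSODA":
            sol = solve_ivp(
                f, (a, b), x, method="Radau", t_eval=t_eval, rtol=rtol, atol=atol
            )
        if not sol.success:
            t_last = sol.t[-1] if sol.t.size else a
            raise IntegrationError(
                f"integration failed in segment [{a}, {b}]: {sol.message}",
                t_last=t_last,
            )
        states[filled:hi] = sol.y.T[: hi - filled]
        x = sol.y[:, -1]
        filled = hi
    if not np.all(np.isfinite(states)):
        raise IntegrationError("trajectory contains non-finite states")
    return Trajectory(times=save_times, states=states, species=list(model.dynamic_species))


def steadystate(
    model: BSTModel,
    input_constant: np.ndarray | None = None,
    tau_abs: float = 1e-8,
    tau_rel: float = 1e-6,
    t_max: float = 1e6,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> SteadyStateResult:
    """Steady state by dynamic settling (forward integration).

    Integrates from ``model.x0`` over successively doubled horizons until
    ``||dx/dt||_inf < tau_abs + tau_rel * ||x||_inf``, then reports the final
    state together with the achieved residual ``||S r + u||_inf``.

    Raises
    ------
    SteadyStateError
        If the criterion is not met by ``t_max`` — the signature of sustained
        oscillation or divergence.  The exception carries the last state and
        residual.
    """
    u = None
    if input_constant is not None:
        u = np.atleast_1d(np.asarray(input_constant, dtype=float))
        if u.size != model.n:
            raise ValueError(f"input vector has length {u.size}, expected {model.n}")
    f = _make_rhs(model, u)
    x = model.x0.copy()
    t, horizon = 0.0, 10.0
    while t < t_max:
        t_next = min(t + horizon, t_max)
        sol = solve_ivp(f, (t, t_next), x, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            sol = solve_ivp(f, (t, t_next), x, method="Radau", rtol=rtol, atol=atol)
        if not sol.success:
            raise SteadyStateError(
                f"settling integration failed at t={t}: {sol.message}",
                x_last=x,
                residual=float(np.max(np.abs(f(t, x)))),
            )
        x = sol.y[:, -1]
        t = sol.t[-1]
        deriv = f(t, x)
        if np.max(np.abs(deriv)) < tau_abs + tau_rel * np.max(np.abs(x)):
            return SteadyStateResult(
                x=x, residual=float(np.max(np.abs(deriv))), t_settle=t
            )
        horizon *= 2.0
    deriv = f(t, x)
    raise SteadyStateError(
        f"no steady state by t_max={t_max:g} "
        f"(residual {np.max(np.abs(deriv)):.3e})",
        x_last=x,
        residual=float(np.max(np.abs(deriv))),
    )


def solve_loglinear(cs: ClassicalSSystem) -> np.ndarray:
    """Analytic steady state of a classical S-system via log coordinates.

    Setting production equal to consumption for each species and taking
    logarithms yields the linear system ``A y = b`` with ``y = ln(x)`` over
    the dynamic species, ``A`` the dynamic block of ``Gc - Hc``, and
    ``b_i = ln(beta_i / alpha_i) - sum_static (Gc - Hc)[i, n+j] ln(xs_j)``.

    Raises
    ------
    np.linalg.LinAlgError-derived error message via ValueError
        if ``A`` is singular (degenerate steady state).
    """
    n = cs.n
    D = cs.Gc - cs.Hc
    A = D[:, :n]
    b = np.log(cs.beta_c / cs.alpha_c)
    if cs.m:
        b = b - D[:, n:] @ np.log(cs.xs)
    try:
        y = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate steady state: {exc}") from exc
    return np.exp(y)
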