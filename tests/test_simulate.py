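"""Rate evaluation, ODE integration, and the two steady-state routes."""

import numpy as np
import pytest

from bstkit.fixtures import (
    branched_pathway_model,
    feedback_pathway_model,
    random_classical_system,
)
from bstkit.model_core import BSTModel, ClassicalSSystem, model_from_classical
from bstkit.simulate import (
    PulseSchedule,
    SteadyStateError,
    evaluate,
    rates,
    rhs,
    solve_loglinear,
    steadystate,
)


def one_species_decay(alpha=0.0, beta=1.0, h=1.0, x0=0.0):
    """dx/dt = alpha - beta * x**h as a two-reaction model."""
    return BSTModel(
        ["X1"], [], ["prod", "cons"],
        S=np.array([[1.0, -1.0]]),
        G=np.array([[0.0, h]]),
        alpha=[alpha, beta],
        x0=[x0],
        xs=[],
    )


class TestRates:
    def test_constant_source_rate(self):
        model = one_species_decay(alpha=10.0, beta=0.0)
        r = rates(np.array([0.0]), model)
        assert r[0] == 10.0  # all-zero exponent column: factor exactly 1 at x=0

    def test_mass_action_product(self, feedback):
        model, _ = feedback
        # r2 = alpha_r2 * X2 * E2 with X2=2, E2=1
        x = np.array([0.0, 2.0, 0.0, 0.0, 0.0])
        r = rates(x, model)
        assert r[model.reaction_index("r2")] == pytest.approx(20.0)

    def test_negative_order_feedback(self, feedback):
        model, _ = feedback
        # r1 = 10 * X1 * E1 * X4^-0.5 with X1=1, X4=4 -> 10 * 0.5 = 5
        x = np.array([1.0, 0.0, 0.0, 4.0, 0.0])
        r = rates(x, model)
        assert r[model.reaction_index("r1")] == pytest.approx(5.0)

    def test_mass_action_limit_exact(self):
        """With exponents equal to reactant multiplicities the power law is
        the textbook mass-action rate."""
        model = BSTModel(
            ["A", "B"], [], ["r1"],
            S=np.array([[-2.0], [-1.0]]),
            G=np.array([[2.0], [1.0]]),
            alpha=[3.0],
            x0=[1.0, 1.0],
            xs=[],
        )
        x = np.array([1.7, 0.9])
        assert rates(x, model)[0] == pytest.approx(3.0 * 1.7**2 * 0.9, rel=1e-15)

    def test_non_finite_state_rejected(self, feedback):
        model, _ = feedback
        with pytest.raises(ValueError):
            rates(np.array([1.0, np.nan, 0, 0, 0]), model)


class TestRhs:
    def test_zero_alpha_zero_derivative(self, feedback):
        model, _ = feedback
        model.alpha[:] = 0.0
        np.testing.assert_array_equal(rhs(0.0, model.x0, model), np.zeros(5))

    def test_linear_relaxation_form(self):
        model = one_species_decay()
        sched = PulseSchedule(baseline=[1.0])
        assert rhs(0.0, np.array([0.25]), model, sched)[0] == pytest.approx(0.75)

    def test_pulse_hits_first_channel_only(self, feedback):
        model, sched = feedback
        base = rhs(10.0, model.x0, model)  # inside the high pulse
        driven = rhs(10.0, model.x0, model, sched)
        delta = driven - base
        assert delta[0] == pytest.approx(10.0)
        np.testing.assert_allclose(delta[1:], 0.0, atol=1e-14)

    def test_channel_count_mismatch(self, feedback):
        model, _ = feedback
        with pytest.raises(ValueError):
            rhs(0.0, model.x0, model, PulseSchedule(baseline=[1.0]))


class TestPulseSchedule:
    def test_value_inside_and_outside_pulse(self):
        sched = PulseSchedule(baseline=[1.0], pulses=[[(5.0, 15.0, 10.0)]])
        assert sched.value(4.9)[0] == 1.0
        assert sched.value(5.0)[0] == 10.0
        assert sched.value(15.0)[0] == 1.0

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PulseSchedule(baseline=[0.0], pulses=[[(0.0, 2.0, 1.0), (1.0, 3.0, 2.0)]])

    def test_degenerate_pulse_rejected(self):
        with pytest.raises(ValueError):
            PulseSchedule(baseline=[0.0], pulses=[[(2.0, 2.0, 1.0)]])

    def test_scale_multiplies_everything(self):
        sched = PulseSchedule(baseline=[2.0], pulses=[[(0.0, 1.0, 6.0)]], scale=0.5)
        assert sched.value(0.5)[0] == 3.0
        assert sched.value(2.0)[0] == 1.0


class TestEvaluate:
    def test_all_zero_alpha_constant_trajectory(self, feedback):
        model, _ = feedback
        model.alpha[:] = 0.0
        model.x0[:] = 0.3
        traj = evaluate(model, (0.0, 5.0))
        np.testing.assert_allclose(traj.states, 0.3, atol=1e-9)

    def test_exponential_relaxation_closed_form(self):
        model = one_species_decay()
        sched = PulseSchedule(baseline=[1.0])
        traj = evaluate(model, (0.0, 10.0), input=sched)
        exact = 1.0 - np.exp(-traj.times)
        assert np.max(np.abs(traj.states[:, 0] - exact)) < 1e-6

    def test_default_grid_has_1001_points(self, feedback):
        model, sched = feedback
        traj = evaluate(model, (0.0, 50.0), input=sched)
        assert traj.times.size == 1001
        assert np.all(np.isfinite(traj.states))

    def test_nonnegativity_from_nonnegative_start(self, feedback):
        model, sched = feedback
        traj = evaluate(model, (0.0, 50.0), input=sched)
        assert traj.states.min() >= -10 * 1e-10

    def test_invalid_tspan(self, feedback):
        model, _ = feedback
        with pytest.raises(ValueError):
            evaluate(model, (5.0, 5.0))

    def test_csv_export_header(self, tmp_path, feedback):
        model, sched = feedback
        traj = evaluate(model, (0.0, 1.0), input=sched,
                        save_times=np.linspace(0, 1, 11))
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "time,X1,X2,X3,X4,X5"


class TestSteadyState:
    def test_linear_input_balance(self):
        # dx/dt = 2 - x -> xss = 2
        model = one_species_decay(x0=0.0)
        res = steadystate(model, input_constant=[2.0])
        assert res.x[0] == pytest.approx(2.0, rel=1e-5)
        assert res.residual < 1e-7

    def test_one_species_closed_form(self):
        # alpha=4, beta=1, g=0, h=2 -> xss = (4/1)**(1/2) = 2
        model = one_species_decay(alpha=4.0, beta=1.0, h=2.0, x0=0.5)
        res = steadystate(model)
        assert res.x[0] == pytest.approx(2.0, rel=1e-6)

    def test_nonconvergence_raises_with_state(self):
        # pure growth never settles
        model = BSTModel(["X1"], [], ["prod"], S=np.array([[1.0]]),
                         G=np.array([[0.0]]), alpha=[1.0], x0=[0.0], xs=[])
        with pytest.raises(SteadyStateError) as err:
            steadystate(model, t_max=100.0)
        assert err.value.residual > 0.1
        assert err.value.x_last[0] > 50.0


class TestLogLinear:
    def test_identity_case(self):
        cs = ClassicalSSystem([2.0, 3.0], [2.0, 3.0], np.zeros((2, 2)),
                              np.eye(2), [])
        np.testing.assert_allclose(solve_loglinear(cs), 1.0)

    def test_one_species_closed_form(self):
        cs = ClassicalSSystem([4.0], [1.0], [[0.0]], [[2.0]], [])
        assert solve_loglinear(cs)[0] == pytest.approx(2.0, rel=1e-12)

    def test_static_species_enter_rhs(self):
        # dx/dt = 2*E - x with E=4 -> xss = 8
        cs = ClassicalSSystem([2.0], [1.0], [[0.0, 1.0]], [[1.0, 0.0]], [4.0])
        assert solve_loglinear(cs)[0] == pytest.approx(8.0, rel=1e-12)

    def test_singular_system_rejected(self):
        cs = ClassicalSSystem([2.0], [1.0], [[1.0]], [[1.0]], [])
        with pytest.raises(ValueError, match="degenerate"):
            solve_loglinear(cs)

    @pytest.mark.parametrize("seed", range(8))
    def test_cross_oracle_settling_vs_loglinear(self, seed):
        """Dynamic settling and the log-linear solve are independent routes
        to the same steady state on stable classical systems."""
        cs = random_classical_system(4, m=1, seed=seed)
        model = model_from_classical(cs)
        xss_lin = solve_loglinear(cs)
        res = steadystate(model)
        np.testing.assert_allclose(res.x, xss_lin, rtol=1e-5)


class TestBranchedPathway:
    def test_symmetric_branch_gives_equal_products(self):
        model = branched_pathway_model(E3=1.0, E4=1.0)
        res = steadystate(model)
        d = res.x[model.dynamic_species.index("D")]
        e = res.x[model.dynamic_species.index("E")]
        assert d == pytest.approx(e, rel=1e-4)

    def test_enzyme_sweep_redistributes_flux(self):
        sweep = np.linspace(0.1, 5.0, 15)
        D, E, C = [], [], []
        for e3 in sweep:
            model = branched_pathway_model(E3=float(e3), E4=1.0)
            res = steadystate(model)
            x = dict(zip(model.dynamic_species, res.x))
            D.append(x["D"]); E.append(x["E"]); C.append(x["C"])
        D, E, C = map(np.array, (D, E, C))
        assert np.all(np.diff(D) > 0), "D branch must rise with E3"
        assert np.all(np.diff(E) < 0), "E branch must fall with E3"
        assert np.all(np.diff(C) < 0), "branch metabolite C falls monotonically"
        crossings = np.sum(np.diff(np.sign(D - E)) != 0)
        assert crossings == 1
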