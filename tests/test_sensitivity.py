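"""Morris screening and Sobol indices against analytic oracles."""

import numpy as np
import pytest

from bstkit.fixtures import feedback_parameter_map, feedback_pathway_model
from bstkit.model_core import BSTModel
from bstkit.sensitivity import (
    ParameterMap,
    ParameterTarget,
    make_objective,
    morris,
    performance_integral,
    sobol,
)
from bstkit.simulate import PulseSchedule

UNIT2 = [(0.0, 1.0), (0.0, 1.0)]


def ishigami(theta, a=7.0, b=0.1):
    x1, x2, x3 = theta
    return np.sin(x1) + a * np.sin(x2) ** 2 + b * x3**4 * np.sin(x1)


def ishigami_indices(a=7.0, b=0.1):
    """Closed-form variance decomposition of the Ishigami function on
    [-pi, pi]^3 (independent uniform inputs), derived by direct integration
    of the ANOVA terms."""
    V1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
    V2 = a**2 / 8
    V13 = 8 * b**2 * np.pi**8 / 225
    V = V1 + V2 + V13
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    return S1, ST


class TestPerformanceIntegral:
    def test_constant_trajectory(self):
        model = BSTModel(["X1"], [], ["r"], S=np.array([[1.0]]),
                         G=np.array([[0.0]]), alpha=[0.0], x0=[2.5], xs=[])
        J = performance_integral(model, (0.0, 20.0), None, "X1", 20.0)
        assert J == pytest.approx(50.0, rel=1e-9)

    def test_linear_ramp(self):
        # dx/dt = 1 -> x(t) = t, integral over [0, 20] = 200
        model = BSTModel(["X1"], [], ["r"], S=np.array([[1.0]]),
                         G=np.array([[0.0]]), alpha=[1.0], x0=[0.0], xs=[])
        J = performance_integral(model, (0.0, 20.0), None, "X1", 20.0)
        assert J == pytest.approx(200.0, abs=1e-6)

    def test_unknown_species(self):
        model = BSTModel(["X1"], [], ["r"], S=np.array([[1.0]]),
                         G=np.array([[0.0]]), alpha=[1.0], x0=[0.0], xs=[])
        with pytest.raises(KeyError):
            performance_integral(model, (0.0, 20.0), None, "NOPE", 20.0)


class TestParameterMap:
    def test_apply_is_pure(self, feedback):
        model, sched = feedback
        pmap = feedback_parameter_map()
        theta = np.array([1.2, 8.0, 9.0, 11.0, 2.0, 0.08, -1.0])
        m2, inp2 = pmap.apply(model, sched, theta)
        assert model.alpha[model.reaction_index("r1")] == 10.0  # untouched
        assert m2.alpha[m2.reaction_index("r1")] == 8.0
        assert m2.G[m2.species_index("X4"), m2.reaction_index("r1")] == -1.0
        assert inp2.scale == 1.2 and sched.scale == 1.0

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError, match="lower bound"):
            ParameterMap([ParameterTarget("alpha", "r1")], [2.0], [1.0])

    def test_unresolvable_target_rejected(self, feedback):
        model, _ = feedback
        pmap = ParameterMap([ParameterTarget("alpha", "rZ")], [0.0], [1.0])
        with pytest.raises(KeyError):
            pmap.check(model)

    def test_input_scale_requires_schedule(self, feedback):
        model, _ = feedback
        pmap = ParameterMap([ParameterTarget("input_scale")], [0.5], [1.5])
        with pytest.raises(ValueError, match="input"):
            pmap.apply(model, None, np.array([1.0]))


class TestMorris:
    def test_linear_function_constant_effects(self):
        f = lambda th: 3.0 * th[0]
        res = morris(f, UNIT2, trajectories=20, seed=0, names=["a", "b"])
        assert res.mu_star[0] == pytest.approx(3.0, abs=1e-12)
        assert res.mu[0] == pytest.approx(3.0, abs=1e-12)
        assert res.sigma2[0] == pytest.approx(0.0, abs=1e-12)
        assert res.mu_star[1] == pytest.approx(0.0, abs=1e-12)

    def test_interaction_inflates_variance(self):
        f = lambda th: th[0] * th[1]
        res = morris(f, UNIT2, trajectories=60, seed=1)
        assert res.sigma2[0] > 0.01

    def test_signed_mean_bounded_by_mu_star(self):
        f = lambda th: np.sin(5 * th[0]) - th[1] ** 2
        res = morris(f, UNIT2, trajectories=40, seed=2)
        assert np.all(res.mu_star >= np.abs(res.mu) - 1e-12)
        assert np.all(res.sigma2 >= 0)

    def test_additive_shift_invariance(self):
        f = lambda th: th[0] + 0.5 * th[1]
        g = lambda th: f(th) + 42.0
        a = morris(f, UNIT2, trajectories=25, seed=3)
        b = morris(g, UNIT2, trajectories=25, seed=3)
        np.testing.assert_allclose(a.mu, b.mu, atol=1e-12)
        np.testing.assert_allclose(a.mu_star, b.mu_star, atol=1e-12)
        np.testing.assert_allclose(a.sigma2, b.sigma2, atol=1e-10)

    def test_fixed_seed_bit_identical(self):
        f = lambda th: th[0] ** 2 + th[1]
        a = morris(f, UNIT2, trajectories=15, seed=7)
        b = morris(f, UNIT2, trajectories=15, seed=7)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_odd_levels_rejected(self):
        with pytest.raises(ValueError):
            morris(lambda th: th[0], UNIT2, trajectories=5, levels=3)


class TestSobol:
    def test_additive_function_analytic_indices(self):
        # f = th0 + 2*th1 on U(0,1)^2: S1 = ST = a_i^2 / sum a_j^2
        f = lambda th: th[0] + 2.0 * th[1]
        res = sobol(f, UNIT2, base_samples=512, seed=0, bootstrap=100)
        assert res.S1[0] == pytest.approx(0.2, abs=0.03)
        assert res.S1[1] == pytest.approx(0.8, abs=0.03)
        np.testing.assert_allclose(res.ST, res.S1, atol=0.03)

    def test_ishigami_closed_form(self):
        bounds = [(-np.pi, np.pi)] * 3
        res = sobol(ishigami, bounds, base_samples=4096, seed=1, bootstrap=50)
        S1_exact, ST_exact = ishigami_indices()
        np.testing.assert_allclose(res.S1, S1_exact, atol=0.05)
        np.testing.assert_allclose(res.ST, ST_exact, atol=0.05)

    def test_index_inequalities(self):
        res = sobol(ishigami, [(-np.pi, np.pi)] * 3, base_samples=1024, seed=2,
                    bootstrap=50)
        slack = 0.05
        assert res.S1.sum() <= 1 + slack
        assert np.all(res.ST >= res.S1 - slack)

    def test_output_scaling_invariance(self):
        f = lambda th: th[0] + th[1] ** 2
        a = sobol(f, UNIT2, base_samples=256, seed=3, bootstrap=10)
        scaled = sobol(lambda th: 100.0 * f(th), UNIT2, base_samples=256,
                       seed=3, bootstrap=10)
        np.testing.assert_allclose(a.S1, scaled.S1, atol=1e-10)
        np.testing.assert_allclose(a.ST, scaled.ST, atol=1e-10)
        # an additive shift cancels only in expectation for the S1 estimator
        shifted = sobol(lambda th: f(th) + 5.0, UNIT2, base_samples=256,
                        seed=3, bootstrap=10)
        np.testing.assert_allclose(a.S1, shifted.S1, atol=0.01)
        np.testing.assert_allclose(a.ST, shifted.ST, atol=1e-10)

    def test_zero_variance_flagged_degenerate(self):
        res = sobol(lambda th: 1.0, UNIT2, base_samples=64, seed=4, bootstrap=10)
        assert res.degenerate
        np.testing.assert_array_equal(res.S1, 0.0)
        np.testing.assert_array_equal(res.ST, 0.0)

    def test_fixed_seed_bit_identical(self):
        f = lambda th: th[0] * th[1] + th[0]
        a = sobol(f, UNIT2, base_samples=128, seed=5, bootstrap=20)
        b = sobol(f, UNIT2, base_samples=128, seed=5, bootstrap=20)
        assert np.array_equal(a.S1, b.S1)
        assert np.array_equal(a.ST_ci, b.ST_ci)


class TestObjective:
    def test_nominal_parameters_reproduce_plain_run(self, feedback):
        model, sched = feedback
        pmap = feedback_parameter_map()
        f = make_objective(model, pmap, input=sched, tspan=(0.0, 20.0),
                           species="X4", rtol=1e-8, atol=1e-10)
        nominal = np.array([1.0, 10.0, 10.0, 10.0, 3.0, 0.1, -0.5])
        direct = performance_integral(model, (0.0, 20.0), sched, "X4", 20.0)
        assert f(nominal) == pytest.approx(direct, rel=1e-7)

    def test_result_export(self, tmp_path):
        f = lambda th: th[0] + th[1]
        res = sobol(f, UNIT2, base_samples=64, seed=6, bootstrap=10,
                    names=["a", "b"])
        res.to_csv(tmp_path / "s.csv")
        lines = (tmp_path / "s.csv").read_text().splitlines()
        assert lines[0].startswith("parameter,S1")
        assert len(lines) == 3
        payload = res.to_json(tmp_path / "s.json")
        assert set(payload["parameters"]) == {"a", "b"}
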