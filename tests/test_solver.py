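"""Stiff integration, steady states and Jacobian evaluation."""

import numpy as np
import pytest

from odesens import (
    IntegrationFailureError,
    NotSupportedError,
    SolverConfig,
    find_steady_state,
    get_fixture,
    jacobian_at,
    simulate,
)
from odesens.codegen import compile_model
from odesens.model import Model, reactions_to_odes, sym

import sympy as sp


def nominal(cm):
    m = cm.model
    p = m.nominal_parameters()
    k = m.nominal_fixed_parameters()
    return p, k, cm.x0(p, k)


class TestSimulate:
    def test_decay_matches_exponential(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        cfg = SolverConfig()
        traj = simulate(cm, p, k, x0, [0.0, 1.0], cfg)
        assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), abs=10 * cfg.rtol)

    def test_conversion_conserves_total(self, fixture_models):
        _, cm = fixture_models["conversion"]
        p, k, x0 = nominal(cm)
        traj = simulate(cm, p, k, x0, np.linspace(0, 3, 40))
        totals = traj.states.sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-8)

    def test_lotka_volterra_against_high_accuracy_reference(self, fixture_models):
        """Default-tolerance run agrees with an rtol=1e-12 self-reference."""
        _, cm = fixture_models["lotka_volterra"]
        p, k, x0 = nominal(cm)
        ref = simulate(cm, p, k, x0, [0.0, 5.0], SolverConfig(rtol=1e-12, atol=1e-14))
        got = simulate(cm, p, k, x0, [0.0, 5.0], SolverConfig())
        rel = np.max(np.abs(got.states[-1] - ref.states[-1]) / np.abs(ref.states[-1]))
        assert rel < 1e-6

    def test_outputs_recomputable_from_states(self, fixture_models):
        _, cm = fixture_models["lotka_volterra"]
        p, k, x0 = nominal(cm)
        traj = simulate(cm, p, k, x0, np.linspace(0, 2, 10))
        for x_row, y_row in zip(traj.states, traj.outputs):
            np.testing.assert_allclose(y_row, cm.h(x_row, p, k), rtol=1e-14)

    def test_timepoints_must_be_sorted(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        with pytest.raises(ValueError):
            simulate(cm, p, k, x0, [1.0, 0.0])

    def test_max_steps_exhaustion_reports_failure_time(self, fixture_models):
        _, cm = fixture_models["lotka_volterra"]
        p, k, x0 = nominal(cm)
        with pytest.raises(IntegrationFailureError) as err:
            simulate(cm, p, k, x0, [0.0, 50.0], SolverConfig(max_steps=5))
        assert err.value.t_failure is not None
        assert 0.0 <= err.value.t_failure < 50.0

    def test_iterative_linear_solver_raises_not_supported(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        with pytest.raises(NotSupportedError):
            simulate(cm, p, k, x0, [0.0, 1.0], SolverConfig(linear_solver="iterative"))

    def test_nonstiff_method_agrees_with_stiff(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        stiff = simulate(cm, p, k, x0, [0.0, 1.0], SolverConfig())
        adams = simulate(
            cm, p, k, x0, [0.0, 1.0], SolverConfig(method="nonstiff_multistep")
        )
        np.testing.assert_allclose(
            adams.states[-1], stiff.states[-1], rtol=1e-6
        )

    @pytest.mark.parametrize("name", ["conversion", "lotka_volterra", "linear_chain4"])
    def test_dense_and_sparse_modes_agree(self, fixture_models, name):
        _, cm = fixture_models[name]
        p, k, x0 = nominal(cm)
        cfg = SolverConfig()
        dense = simulate(cm, p, k, x0, np.linspace(0, 3, 15), cfg)
        sparse = simulate(
            cm, p, k, x0, np.linspace(0, 3, 15),
            SolverConfig(linear_solver="sparse"),
        )
        np.testing.assert_allclose(
            sparse.states, dense.states, rtol=10 * cfg.rtol, atol=10 * cfg.atol
        )

    @pytest.mark.parametrize("name", ["decay", "synthesis_degradation", "linear_chain4"])
    def test_tightening_tolerances_does_not_increase_error(self, fixture_models, name):
        """10x tighter tolerances never worsen the analytic-solution error."""
        fx, cm = fixture_models[name]
        p, k, x0 = nominal(cm)
        times = np.linspace(0.0, 3.0, 20)
        ref = np.array([fx.analytic(t, p, k)[0] for t in times])
        errs = []
        for cfg in (SolverConfig(rtol=1e-5, atol=1e-8),
                    SolverConfig(rtol=1e-6, atol=1e-9)):
            traj = simulate(cm, p, k, x0, times, cfg)
            errs.append(np.max(np.abs(traj.states - ref)))
        assert errs[1] <= errs[0] + 1e-14


class TestSteadyState:
    def test_synthesis_degradation_newton(self, fixture_models):
        _, cm = fixture_models["synthesis_degradation"]
        ss = find_steady_state(cm, np.array([4.0]), np.array([2.0]), np.array([0.0]))
        assert ss.method_used == "newton"
        assert ss.x_ss[0] == pytest.approx(0.5, rel=1e-10)
        assert ss.residual_norm < 1.0

    def test_conversion_needs_simulation_due_to_singular_jacobian(self, fixture_models):
        _, cm = fixture_models["conversion"]
        ss = find_steady_state(
            cm, np.array([1.0, 2.0]), np.array([]), np.array([1.0, 0.0])
        )
        assert ss.method_used in ("simulation", "newton_after_simulation")
        np.testing.assert_allclose(ss.x_ss, [2 / 3, 1 / 3], rtol=1e-6)
        assert ss.residual_norm < 1.0

    def test_newton_and_simulation_routes_agree(self, fixture_models):
        _, cm = fixture_models["synthesis_degradation"]
        p, k = np.array([4.0]), np.array([2.0])
        newton = find_steady_state(cm, p, k, np.array([0.0]))
        # force the simulation route by exhausting Newton immediately
        sim = find_steady_state(
            cm, p, k, np.array([0.0]), SolverConfig(newton_max_iters=1)
        )
        np.testing.assert_allclose(sim.x_ss, newton.x_ss, rtol=1e-6)

    def test_random_monotone_decay_systems_converge(self):
        """Property: residual_norm < 1 on any success across sampled systems."""
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = int(rng.integers(1, 5))
            rates = rng.uniform(0.5, 5.0, n)
            states = [f"x{i}" for i in range(n)]
            params = [f"r{i}" for i in range(n)]
            model = Model(
                state_ids=states,
                parameter_ids=params,
                fixed_parameter_ids=[],
                rhs=[-sym(f"r{i}") * sym(f"x{i}") for i in range(n)],
                initials=[sp.Float(v) for v in rng.uniform(0.5, 2.0, n)],
                parameter_values={f"r{i}": rates[i] for i in range(n)},
                name=f"monotone{trial}",
            )
            cm = compile_model(model)
            ss = find_steady_state(cm, rates, np.array([]), cm.x0(rates, np.array([])))
            assert ss.residual_norm < 1.0
            np.testing.assert_allclose(ss.x_ss, 0.0, atol=1e-6)


class TestJacobianAt:
    def test_decay_point_value(self, fixture_models):
        _, cm = fixture_models["decay"]
        J = jacobian_at(cm, np.array([1.0]), np.array([3.0]), np.array([]))
        np.testing.assert_allclose(J, [[-3.0]])

    def test_conversion_point_value(self, fixture_models):
        _, cm = fixture_models["conversion"]
        J = jacobian_at(cm, np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([]))
        np.testing.assert_allclose(J, [[-1.0, 2.0], [1.0, -2.0]])

    def test_sparse_mode_returns_csc(self, fixture_models):
        _, cm = fixture_models["conversion"]
        J = jacobian_at(
            cm, np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([]),
            cfg=SolverConfig(linear_solver="sparse"),
        )
        assert hasattr(J, "tocsc")

    @pytest.mark.parametrize("name", ["lotka_volterra", "linear_chain4"])
    def test_agrees_with_central_finite_differences(self, fixture_models, name):
        _, cm = fixture_models[name]
        rng = np.random.default_rng(3)
        p = cm.model.nominal_parameters()
        k = cm.model.nominal_fixed_parameters()
        for _ in range(3):
            x = rng.uniform(0.3, 2.0, cm.n_states)
            J = jacobian_at(cm, x, p, k)
            h = 1e-6
            fd = np.zeros_like(J)
            for j in range(cm.n_states):
                e = np.zeros(cm.n_states)
                e[j] = h
                fd[:, j] = (cm.f(x + e, p, k) - cm.f(x - e, p, k)) / (2 * h)
            np.testing.assert_allclose(J, fd, rtol=1e-5, atol=1e-8)
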