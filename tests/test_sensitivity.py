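"""Forward, adjoint and steady-state sensitivities and their cross-checks."""

import numpy as np
import pytest
import sympy as sp

from odesens import (
    DataPoint,
    SolverConfig,
    adjoint_gradient,
    compile_model,
    find_steady_state,
    finite_difference_gradient,
    forward_gradient,
    forward_sensitivities,
    get_fixture,
    simulate,
    steadystate_sensitivities,
)
from odesens.model import Model, sym
from tests.conftest import max_rel_diff


def nominal(cm):
    m = cm.model
    p = m.nominal_parameters()
    k = m.nominal_fixed_parameters()
    return p, k, cm.x0(p, k)


class TestForwardSensitivities:
    def test_decay_analytic_sensitivity(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        cfg = SolverConfig()
        fsr = forward_sensitivities(cm, p, k, x0, [0.0, 1.0], cfg)
        # d/dk e^{-kt} = -t e^{-kt}
        assert fsr.sx[-1, 0, 0] == pytest.approx(-np.exp(-1.0), abs=10 * cfg.rtol)

    def test_inert_parameter_has_zero_sensitivity(self):
        x1, k1 = sym("x1"), sym("k1")
        model = Model(
            state_ids=["x1"],
            parameter_ids=["k1", "unused"],
            fixed_parameter_ids=[],
            rhs=[-k1 * x1],
            initials=[sp.Float(1.0)],
            parameter_values={"k1": 1.0, "unused": 7.0},
            observables={"obs": x1},
            noise_formulas={"obs": sp.Float(1.0)},
        )
        cm = compile_model(model)
        fsr = forward_sensitivities(
            cm, np.array([1.0, 7.0]), np.array([]), np.array([1.0]),
            np.linspace(0, 2, 5),
        )
        np.testing.assert_array_equal(fsr.sx[:, :, 1], 0.0)

    def test_output_sensitivity_uses_assembly_code_path(self, fixture_models):
        from odesens.codegen import assemble_output_sensitivity

        _, cm = fixture_models["conversion"]
        p, k, x0 = nominal(cm)
        fsr = forward_sensitivities(cm, p, k, x0, [0.0, 1.0])
        i = 1
        expected = assemble_output_sensitivity(
            cm.dhdx(fsr.trajectory.states[i], p, k),
            fsr.sx[i],
            cm.dhdp(fsr.trajectory.states[i], p, k),
        )
        np.testing.assert_array_equal(fsr.sy[i], expected)

    def test_lotka_volterra_against_finite_differences(self, fixture_models):
        """State sensitivities at t=2 vs central FD of tight reruns."""
        _, cm = fixture_models["lotka_volterra"]
        p, k, x0 = nominal(cm)
        tight = SolverConfig(rtol=1e-10, atol=1e-13)
        fsr = forward_sensitivities(cm, p, k, x0, [0.0, 2.0], tight)
        fd = np.zeros((cm.n_states, cm.n_parameters))
        for j in range(cm.n_parameters):
            h = 1e-5 * abs(p[j])
            for sign in (+1, -1):
                pj = p.copy()
                pj[j] += sign * h
                traj = simulate(cm, pj, k, x0, [0.0, 2.0], tight)
                fd[:, j] += sign * traj.states[-1] / (2 * h)
        assert max_rel_diff(fsr.sx[-1], fd) < 1e-4


class TestAdjointGradient:
    def test_zero_residual_gradient_vanishes(self, fixture_models):
        """At a stationary point of the quadratic residual the gradient is 0."""
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        cfg = SolverConfig(rtol=1e-10, atol=1e-13)
        times = [0.5, 1.0, 1.5]
        traj = simulate(cm, p, k, x0, [0.0] + times, cfg)
        dps = [
            DataPoint(t=t, observable_index=0, value=float(traj.outputs[i + 1, 0]),
                      sigma_override=1.0)
            for i, t in enumerate(times)
        ]
        res = adjoint_gradient(cm, p, k, x0, dps, cfg)
        np.testing.assert_allclose(res.gradient, 0.0, atol=1e-7)

    def test_single_datapoint_matches_forward_method(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        dps = [DataPoint(t=1.0, observable_index=0, value=0.5, sigma_override=1.0)]
        gf = forward_gradient(cm, p, k, x0, dps)
        ga = adjoint_gradient(cm, p, k, x0, dps)
        assert max_rel_diff(gf.gradient, ga.gradient) < 1e-5
        assert gf.value == pytest.approx(ga.value, rel=1e-8)

    def test_twenty_point_lotka_volterra_vs_finite_differences(self, fixture_models):
        _, cm = fixture_models["lotka_volterra"]
        p, k, x0 = nominal(cm)
        cfg = SolverConfig(rtol=1e-10, atol=1e-13)
        rng = np.random.default_rng(17)
        times = np.linspace(0.25, 2.5, 10)
        ref = simulate(cm, p, k, x0, [0.0, *times], cfg)
        dps = []
        for i, t in enumerate(times):
            for iy in range(2):
                dps.append(
                    DataPoint(
                        t=float(t), observable_index=iy,
                        value=float(ref.outputs[i + 1, iy])
                        + 0.05 * rng.standard_normal(),
                        sigma_override=0.05,
                    )
                )
        assert len(dps) == 20
        ga = adjoint_gradient(cm, p, k, x0, dps, cfg)

        def objective(q):
            traj = simulate(cm, q, k, x0, [0.0, *times], cfg)
            from odesens.sensitivity import nll_point

            total = 0.0
            for i, t in enumerate(times):
                for iy in range(2):
                    dp = dps[2 * i + iy]
                    total += nll_point(
                        float(traj.outputs[i + 1, iy]), dp.sigma_override, dp.value
                    )[0]
            return total

        fd = finite_difference_gradient(objective, p)
        assert max_rel_diff(ga.gradient, fd) < 1e-4

    def test_datapoint_before_t0_rejected(self, fixture_models):
        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        with pytest.raises(ValueError):
            adjoint_gradient(
                cm, p, k, x0,
                [DataPoint(t=-1.0, observable_index=0, value=0.5, sigma_override=1.0)],
            )


class TestSteadyStateSensitivities:
    def test_synthesis_degradation_closed_form(self):
        """Implicit-function theorem: dx*/da = 1/b, dx*/db = -a/b^2."""
        x1, a, b = sym("x1"), sym("a"), sym("b")
        model = Model(
            state_ids=["x1"],
            parameter_ids=["a", "b"],
            fixed_parameter_ids=[],
            rhs=[a - b * x1],
            initials=[sp.Float(0.0)],
            parameter_values={"a": 2.0, "b": 4.0},
            observables={"obs": x1},
            noise_formulas={"obs": sp.Float(1.0)},
        )
        cm = compile_model(model)
        p = np.array([2.0, 4.0])
        ss = find_steady_state(cm, p, np.array([]), np.array([0.0]))
        sss = steadystate_sensitivities(cm, ss, p, np.array([]))
        assert sss.method == "linear_solve"
        np.testing.assert_allclose(sss.sx, [[0.25, -0.125]], rtol=1e-12)

    def test_conversion_fallback_matches_long_time_forward(self, fixture_models):
        """Singular J: the simulation fallback equals forward sens at t=1e6."""
        _, cm = fixture_models["conversion"]
        p, k = np.array([1.0, 2.0]), np.array([])
        x0 = np.array([1.0, 0.0])
        ss = find_steady_state(cm, p, k, x0)
        sss = steadystate_sensitivities(cm, ss, p, k, x_init=x0)
        assert sss.fallback_used and sss.method == "simulation"
        fsr = forward_sensitivities(cm, p, k, x0, [0.0, 1e6])
        assert max_rel_diff(sss.sx, fsr.sx[-1]) < 1e-5

    def test_random_stable_linear_systems(self):
        """s* = -A^{-1} B for f = A x + B p, reproduced to 1e-10."""
        rng = np.random.default_rng(11)
        n, n_p = 5, 3
        for trial in range(3):
            M = rng.standard_normal((n, n))
            A = -(M @ M.T + np.eye(n))
            B = rng.standard_normal((n, n_p))
            states = [f"x{i}" for i in range(n)]
            params = [f"p{i}" for i in range(n_p)]
            xs = sp.Matrix([sym(s) for s in states])
            ps = sp.Matrix([sym(q) for q in params])
            rhs_mat = sp.Matrix(A) * xs + sp.Matrix(B) * ps
            model = Model(
                state_ids=states,
                parameter_ids=params,
                fixed_parameter_ids=[],
                rhs=list(rhs_mat),
                initials=[sp.Float(0.0)] * n,
                parameter_values={q: 1.0 for q in params},
                name=f"linear5_{trial}",
            )
            cm = compile_model(model)
            p = rng.uniform(0.5, 1.5, n_p)
            ss = find_steady_state(cm, p, np.array([]), np.zeros(n))
            sss = steadystate_sensitivities(cm, ss, p, np.array([]))
            assert sss.method == "linear_solve"
            np.testing.assert_allclose(
                sss.sx, -np.linalg.solve(A, B), rtol=1e-10, atol=1e-12
            )

    def test_forward_limit_matches_steady_state(self, fixture_models):
        """Forward sensitivities at t=1e6 converge to the implicit solution."""
        _, cm = fixture_models["synthesis_degradation"]
        p, k = np.array([4.0]), np.array([2.0])
        ss = find_steady_state(cm, p, k, np.array([0.0]))
        sss = steadystate_sensitivities(cm, ss, p, k)
        fsr = forward_sensitivities(cm, p, k, np.array([0.0]), [0.0, 1e6])
        assert max_rel_diff(sss.sx, fsr.sx[-1]) < 1e-5


class TestFiniteDifferenceGradient:
    def test_quadratic_objective(self):
        g = finite_difference_gradient(lambda q: float(np.sum(q**2)), np.array([1.0, 2.0]))
        np.testing.assert_allclose(g, [2.0, 4.0], atol=1e-8)

    def test_constant_objective(self):
        g = finite_difference_gradient(lambda q: 3.5, np.array([1.0, -2.0, 0.3]))
        np.testing.assert_array_equal(g, 0.0)

    def test_forward_scheme(self):
        g = finite_difference_gradient(
            lambda q: float(q[0] ** 2), np.array([2.0]), scheme="forward", step=1e-8
        )
        assert g[0] == pytest.approx(4.0, rel=1e-6)

    def test_cross_check_against_forward_method(self, fixture_models):
        from odesens.sensitivity import nll_point

        _, cm = fixture_models["decay"]
        p, k, x0 = nominal(cm)
        dps = [DataPoint(t=1.0, observable_index=0, value=0.3, sigma_override=0.1)]
        gf = forward_gradient(cm, p, k, x0, dps)

        def objective(q):
            traj = simulate(cm, q, k, x0, [0.0, 1.0])
            return nll_point(float(traj.outputs[-1, 0]), 0.1, 0.3)[0]

        fd = finite_difference_gradient(objective, p)
        assert max_rel_diff(gf.gradient, fd) < 1e-4
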