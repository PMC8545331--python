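"""PEtab loading, condition mapping, the NLL objective and its gradients."""

import math

import numpy as np
import pytest
import sympy as sp

from odesens import (
    NotSupportedError,
    PEtabFormatError,
    Presimulation,
    SolverConfig,
    apply_condition,
    equilibrate_and_simulate,
    evaluate_objective,
    export_sbml,
    find_steady_state,
    finite_difference_gradient,
    get_fixture,
    load_petab,
    negloglik,
    objective_and_gradient,
    simulate,
    steadystate_sensitivities,
)
from tests.conftest import max_rel_diff


def write_minimal_bundle(tmp_path, measurements=None, observables=None,
                         conditions=None, parameters=None):
    """A 1-condition decay bundle, overridable piecewise for lint tests."""
    (tmp_path / "model.xml").write_text(export_sbml(get_fixture("decay").model))
    (tmp_path / "conditions.tsv").write_text(
        conditions if conditions is not None else "conditionId\nc1\n"
    )
    (tmp_path / "observables.tsv").write_text(
        observables
        if observables is not None
        else "observableId\tobservableFormula\tnoiseFormula\nobs_x1\tx1\t0.1\n"
    )
    (tmp_path / "measurements.tsv").write_text(
        measurements
        if measurements is not None
        else (
            "observableId\tsimulationConditionId\ttime\tmeasurement\n"
            "obs_x1\tc1\t0.5\t0.6\n"
            "obs_x1\tc1\t1.0\t0.35\n"
            "obs_x1\tc1\t2.0\t0.15\n"
        )
    )
    (tmp_path / "parameters.tsv").write_text(
        parameters
        if parameters is not None
        else (
            "parameterId\tparameterScale\tlowerBound\tupperBound\tnominalValue\testimate\n"
            "k1\tlog10\t0.001\t1000\t1.0\t1\n"
        )
    )
    (tmp_path / "problem.yaml").write_text(
        "format_version: 1\n"
        "parameter_file: parameters.tsv\n"
        "problems:\n"
        "  - sbml_files: [model.xml]\n"
        "    condition_files: [conditions.tsv]\n"
        "    measurement_files: [measurements.tsv]\n"
        "    observable_files: [observables.tsv]\n"
    )
    return tmp_path / "problem.yaml"


class TestLoadPetab:
    def test_minimal_bundle(self, tmp_path):
        prob = load_petab(write_minimal_bundle(tmp_path))
        assert prob.n_conditions == 1
        assert prob.n_measurements == 3
        assert prob.estimated_ids == ["k1"]

    def test_unknown_observable_is_named(self, tmp_path):
        yaml = write_minimal_bundle(
            tmp_path,
            measurements=(
                "observableId\tsimulationConditionId\ttime\tmeasurement\n"
                "obs_ghost\tc1\t1.0\t0.35\n"
            ),
        )
        with pytest.raises(PEtabFormatError) as err:
            load_petab(yaml)
        assert "obs_ghost" in str(err.value)

    def test_missing_column_is_reported(self, tmp_path):
        yaml = write_minimal_bundle(
            tmp_path, measurements="observableId\ttime\tmeasurement\nobs_x1\t1\t0.3\n"
        )
        with pytest.raises(PEtabFormatError) as err:
            load_petab(yaml)
        assert "simulationConditionId" in str(err.value)

    def test_negative_time_rejected(self, tmp_path):
        yaml = write_minimal_bundle(
            tmp_path,
            measurements=(
                "observableId\tsimulationConditionId\ttime\tmeasurement\n"
                "obs_x1\tc1\t-1.0\t0.35\n"
            ),
        )
        with pytest.raises(PEtabFormatError):
            load_petab(yaml)

    def test_condition_overriding_estimated_parameter_rejected(self, tmp_path):
        yaml = write_minimal_bundle(
            tmp_path, conditions="conditionId\tk1\nc1\t5.0\n"
        )
        with pytest.raises(PEtabFormatError) as err:
            load_petab(yaml)
        assert "k1" in str(err.value)

    def test_species_initial_override_reflected_in_x0(self, tmp_path):
        yaml = write_minimal_bundle(
            tmp_path, conditions="conditionId\tx1\nc1\t2.5\n"
        )
        prob = load_petab(yaml)
        applied = apply_condition(prob, "c1", prob.nominal_estimated())
        assert applied.x0[0] == 2.5
        np.testing.assert_array_equal(applied.sx0[0], 0.0)


class TestApplyCondition:
    def test_log10_scale_backtransform(self, tmp_path):
        prob = load_petab(write_minimal_bundle(tmp_path))
        applied = apply_condition(prob, "c1", np.array([0.0]))
        assert applied.p[0] == 1.0  # 10**0

    def test_fixed_parameter_override(self, petab_problems):
        prob = petab_problems["preeq"]
        p_est = prob.nominal_estimated()
        a_index = prob.model.fixed_parameter_ids.index("a")
        main = apply_condition(prob, "main", p_est)
        pre = apply_condition(prob, "preeq", p_est)
        assert main.k[a_index] == 0.0
        assert pre.k[a_index] == 2.0

    def test_no_overrides_pass_nominals_through(self, petab_problems):
        prob = petab_problems["conversion"]
        applied = apply_condition(prob, "main", prob.nominal_estimated())
        np.testing.assert_array_equal(applied.p, [1.0, 2.0])


class TestPipeline:
    def test_without_preeq_identical_to_plain_simulate(self, petab_problems):
        prob = petab_problems["decay"]
        p_est = prob.nominal_estimated()
        applied = apply_condition(prob, "main", p_est)
        times = [0.0, 0.5, 1.0]
        traj = equilibrate_and_simulate(prob, "main", p_est, timepoints=times)
        direct = simulate(prob.compiled, applied.p, applied.k, applied.x0, times)
        np.testing.assert_array_equal(traj.states, direct.states)

    def test_two_phase_analytic(self, petab_problems):
        """Equilibrate at (a=2, b=4) then decay: x(t) = 0.5 exp(-4t)."""
        prob = petab_problems["preeq"]
        p_est = prob.nominal_estimated()  # b = 4 on log10 scale
        times = np.linspace(0.0, 1.0, 11)
        traj = equilibrate_and_simulate(
            prob, "main", p_est, timepoints=times,
            preequilibration_condition_id="preeq",
        )
        expected = 0.5 * np.exp(-4.0 * times)
        np.testing.assert_allclose(traj.states[:, 0], expected, atol=1e-7)

    def test_preeq_sensitivity_equals_steady_state_solution(self, petab_problems):
        prob = petab_problems["preeq"]
        p_est = prob.nominal_estimated()
        fsr = equilibrate_and_simulate(
            prob, "main", p_est, want_sensitivities=True, timepoints=[0.0],
            preequilibration_condition_id="preeq",
        )
        pre = apply_condition(prob, "preeq", p_est)
        ss = find_steady_state(prob.compiled, pre.p, pre.k, pre.x0)
        sss = steadystate_sensitivities(
            prob.compiled, ss, pre.p, pre.k, x_init=pre.x0, sx_init=pre.sx0
        )
        np.testing.assert_allclose(fsr.sx[0], sss.sx, rtol=1e-6, atol=1e-10)

    def test_presimulation_two_phase_analytic(self, petab_problems):
        """Pre-simulate synthesis for T=1 from x0=0, then pure decay."""
        prob = petab_problems["preeq"]
        cond = prob.conditions["main"]
        cond.presimulation = Presimulation(duration=1.0, overrides={"a": 2.0})
        try:
            p_est = prob.nominal_estimated()
            b = 4.0
            times = np.linspace(0.0, 1.0, 6)
            traj = equilibrate_and_simulate(prob, "main", p_est, timepoints=times)
            x_pe = (2.0 / b) * (1.0 - np.exp(-b * 1.0))
            np.testing.assert_allclose(
                traj.states[:, 0], x_pe * np.exp(-b * times), atol=1e-7
            )
            # forward sensitivities propagate through the pre-simulation phase
            fsr = equilibrate_and_simulate(
                prob, "main", p_est, want_sensitivities=True, timepoints=times
            )
            t_sym, b_sym = sp.symbols("t b", real=True)
            x_expr = (2 / b_sym) * (1 - sp.exp(-b_sym)) * sp.exp(-b_sym * t_sym)
            dxdb = sp.lambdify((t_sym, b_sym), sp.diff(x_expr, b_sym))
            np.testing.assert_allclose(
                fsr.sx[:, 0, 0], [dxdb(t, b) for t in times], atol=1e-6
            )
            with pytest.raises(NotSupportedError):
                objective_and_gradient(prob, p_est, "adjoint")
        finally:
            cond.presimulation = None


class TestNegLogLik:
    def test_zero_residual_unit_sigma(self):
        g = negloglik([1.0], [1.0], 1.0)
        assert g == pytest.approx(0.5 * math.log(2 * math.pi), abs=1e-12)
        assert g == pytest.approx(0.9189385, abs=1e-7)

    def test_one_sigma_residual_adds_half(self):
        base = negloglik([1.0], [1.0], 0.3)
        assert negloglik([1.0], [1.3], 0.3) - base == pytest.approx(0.5, abs=1e-12)

    def test_three_point_hand_computed_total(self):
        y = [1.0, 2.0, 0.5]
        ybar = [1.2, 1.5, 0.9]
        sig = [1.0, 2.0, 0.5]
        expected = sum(
            0.5 * ((m - s) / sd) ** 2 + 0.5 * math.log(2 * math.pi * sd**2)
            for s, m, sd in zip(y, ybar, sig)
        )
        assert negloglik(y, ybar, sig) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            negloglik([1.0], [1.0], 0.0)

    def test_lognormal_matches_manual_formula(self):
        y, ybar, s = 2.0, 2.5, 0.3
        expected = (
            0.5 * ((math.log(ybar) - math.log(y)) / s) ** 2
            + 0.5 * math.log(2 * math.pi * s**2)
            + math.log(ybar)
        )
        got = negloglik([y], [ybar], s, distributions=["lognormal"])
        assert got == pytest.approx(expected, abs=1e-12)


class TestObjectiveAndGradient:
    def test_value_is_bit_identical_across_methods(self, petab_problems):
        prob = petab_problems["conversion"]
        p_est = prob.nominal_estimated()
        gf = objective_and_gradient(prob, p_est, "forward")
        ga = objective_and_gradient(prob, p_est, "adjoint")
        assert gf.value == ga.value

    def test_forward_and_adjoint_gradients_agree(self, petab_problems):
        prob = petab_problems["preeq"]
        p_est = prob.nominal_estimated()
        cfg = SolverConfig(rtol=1e-10, atol=1e-13)
        gf = objective_and_gradient(prob, p_est, "forward", cfg)
        ga = objective_and_gradient(prob, p_est, "adjoint", cfg)
        assert max_rel_diff(gf.gradient, ga.gradient) < 1e-4

    def test_duplicated_condition_doubles_value_and_gradient(
        self, petab_bundles, tmp_path
    ):
        import shutil

        src = petab_bundles["conversion"]["yaml"].parent
        dst = tmp_path / "doubled"
        shutil.copytree(src, dst)
        (dst / "conditions.tsv").write_text("conditionId\nmain\nmain2\n")
        meas = (dst / "measurements.tsv").read_text().rstrip("\n").split("\n")
        extra = [row.replace("\tmain\t", "\tmain2\t") for row in meas[1:]]
        (dst / "measurements.tsv").write_text("\n".join(meas + extra) + "\n")
        single = load_petab(petab_bundles["conversion"]["yaml"])
        doubled = load_petab(dst / "problem.yaml")
        p_est = single.nominal_estimated()
        r1 = objective_and_gradient(single, p_est, "forward")
        r2 = objective_and_gradient(doubled, p_est, "forward")
        assert r2.value == r1.value + r1.value
        np.testing.assert_array_equal(r2.gradient, r1.gradient + r1.gradient)

    def test_row_and_condition_order_do_not_change_a_digit(self, petab_bundles):
        prob_a = load_petab(petab_bundles["preeq"]["yaml"])
        prob_b = load_petab(petab_bundles["preeq"]["yaml"])
        prob_b.measurements = list(reversed(prob_b.measurements))
        prob_b.conditions = dict(reversed(list(prob_b.conditions.items())))
        p_est = prob_a.nominal_estimated()
        ra = objective_and_gradient(prob_a, p_est, "forward")
        rb = objective_and_gradient(prob_b, p_est, "forward")
        assert ra.value == rb.value
        np.testing.assert_array_equal(ra.gradient, rb.gradient)

    def test_gradient_matches_finite_differences(self, petab_problems):
        prob = petab_problems["decay_noise"]
        p_est = prob.nominal_estimated()
        cfg = SolverConfig(rtol=1e-10, atol=1e-13)
        gf = objective_and_gradient(prob, p_est, "forward", cfg)
        fd = finite_difference_gradient(
            lambda q: evaluate_objective(prob, q, cfg), p_est
        )
        assert max_rel_diff(gf.gradient, fd) < 1e-4

    def test_log10_gradient_is_linear_gradient_times_p_ln10(
        self, petab_bundles, tmp_path
    ):
        import shutil

        src = petab_bundles["decay"]["yaml"].parent
        dst = tmp_path / "linscale"
        shutil.copytree(src, dst)
        pars = (dst / "parameters.tsv").read_text().replace("log10", "lin")
        (dst / "parameters.tsv").write_text(pars)
        prob_log = load_petab(petab_bundles["decay"]["yaml"])
        prob_lin = load_petab(dst / "problem.yaml")
        g_log = objective_and_gradient(prob_log, prob_log.nominal_estimated(), "forward")
        g_lin = objective_and_gradient(prob_lin, prob_lin.nominal_estimated(), "forward")
        p_lin = prob_lin.nominal_estimated()  # linear-scale nominal values
        expected = g_lin.gradient * p_lin * math.log(10.0)
        assert max_rel_diff(g_log.gradient, expected) < 1e-12

    def test_on_failure_inf_policy(self, petab_problems):
        prob = petab_problems["lotka_volterra"]
        cfg = SolverConfig(max_steps=3)
        res = objective_and_gradient(
            prob, prob.nominal_estimated(), "forward", cfg, on_failure="inf"
        )
        assert math.isinf(res.value)

    def test_on_failure_error_names_condition(self, petab_problems):
        from odesens import ObjectiveEvaluationError

        prob = petab_problems["lotka_volterra"]
        cfg = SolverConfig(max_steps=3)
        with pytest.raises(ObjectiveEvaluationError) as err:
            objective_and_gradient(prob, prob.nominal_estimated(), "forward", cfg)
        assert "main" in str(err.value)
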