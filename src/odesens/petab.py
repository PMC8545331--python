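"""PEtab v1 problems: loading, condition mapping and the NLL objective.

A PEtab problem bundles an SBML model with TSV tables of conditions,
observables, measurements and parameters (plus a YAML index). This module
assembles an :class:`EstimationProblem`, maps conditions onto the model
(including pre-equilibration and pre-simulation), and evaluates the negative
log-likelihood and its gradient aggregated over conditions.

After loading, the model's dynamic parameters are exactly the estimated
parameters (condition tables may only override fixed parameters and species
initial values), so forward/adjoint sensitivities are computed for precisely
the quantities the optimiser needs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp
import yaml

from .codegen import CompiledModel, compile_model
from .exceptions import (
    NotSupportedError,
    ObjectiveEvaluationError,
    OdesensError,
    PEtabFormatError,
)
from .model import Model, sym
from .sbml import import_sbml
from .sensitivity import (
    DataPoint,
    GradientResult,
    adjoint_gradient,
    forward_gradient,
    forward_sensitivities,
    nll_point,
    steadystate_sensitivities,
)
from .solver import SolverConfig, Trajectory, find_steady_state, simulate

_SCALES = ("lin", "log", "log10")


@dataclass
class Presimulation:
    duration: float
    overrides: dict = field(default_factory=dict)


@dataclass
class Condition:
    id: str
    overrides: dict = field(default_factory=dict)  # target id -> number | parameter id
    preequilibration_condition_id: str | None = None
    presimulation: Presimulation | None = None


@dataclass
class ParameterSpec:
    id: str
    nominal: float
    scale: str = "lin"
    lower: float = -math.inf
    upper: float = math.inf
    estimate: bool = True


@dataclass
class MeasurementRow:
    condition_id: str
    preequilibration_condition_id: str | None
    observable_instance: int   # index into the augmented model's observables
    time: float
    value: float
    distribution: str          # normal | lognormal


@dataclass
class EstimationProblem:
    model: Model               # augmented: observable instances, p == estimated
    compiled: CompiledModel
    conditions: dict           # id -> Condition
    measurements: list         # list[MeasurementRow]
    parameters: list           # list[ParameterSpec], estimated first-class
    observable_meta: dict = field(default_factory=dict)

    @property
    def estimated_ids(self):
        return [p.id for p in self.parameters if p.estimate]

    @property
    def n_conditions(self):
        return len(self.conditions)

    @property
    def n_measurements(self):
        return len(self.measurements)

    def parameter(self, pid) -> ParameterSpec:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def nominal_estimated(self, scale=True):
        """Nominal values of the estimated parameters, optionally on scale."""
        out = []
        for p in self.parameters:
            if not p.estimate:
                continue
            out.append(to_scale(p.nominal, p.scale) if scale else p.nominal)
        return np.array(out)


def to_scale(value, scale):
    if scale == "lin":
        return float(value)
    if scale == "log":
        return math.log(value)
    if scale == "log10":
        return math.log10(value)
    raise ValueError(f"unknown parameter scale {scale!r}")


def from_scale(value, scale):
    if scale == "lin":
        return float(value)
    if scale == "log":
        return math.exp(value)
    if scale == "log10":
        return 10.0 ** value
    raise ValueError(f"unknown parameter scale {scale!r}")


def scale_chain_factor(p_linear, scale):
    """d(p_linear)/d(p_scaled): 1, p, or p·ln(10)."""
    if scale == "lin":
        return 1.0
    if scale == "log":
        return p_linear
    if scale == "log10":
        return p_linear * math.log(10.0)
    raise ValueError(f"unknown parameter scale {scale!r}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_FORMULA_LOCALS = {"exp": sp.exp, "log": sp.log, "log10": lambda a: sp.log(a, 10),
                   "sqrt": sp.sqrt, "sin": sp.sin, "cos": sp.cos, "abs": sp.Abs,
                   "pow": sp.Pow}


def _parse_formula(text, where, errors):
    try:
        expr = sp.sympify(str(text), locals=dict(_FORMULA_LOCALS))
        # canonicalise onto the model's real-valued symbols
        return expr.xreplace({s: sym(s.name) for s in expr.free_symbols})
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        errors.append(f"{where}: cannot parse formula {text!r} ({exc})")
        return sp.Integer(0)


def _read_tsv(path, what, required, errors):
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        errors.append(f"{what} table {path}: {exc}")
        return None
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{what} table {path}: missing column(s) {', '.join(missing)}")
        return None
    return df


def _is_number(text):
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


def load_petab(yaml_path) -> EstimationProblem:
    """Load and cross-validate a PEtab v1 problem bundle.

    All lint violations are collected and raised together as a single
    :class:`PEtabFormatError`.
    """
    yaml_path = Path(yaml_path)
    with open(yaml_path) as fh:
        index = yaml.safe_load(fh)
    base = yaml_path.parent
    errors = []

    try:
        prob = index["problems"][0]
        sbml_file = base / prob["sbml_files"][0]
        cond_file = base / prob["condition_files"][0]
        meas_file = base / prob["measurement_files"][0]
        obs_file = base / prob["observable_files"][0]
        par_file = base / index["parameter_file"]
    except (KeyError, IndexError, TypeError) as exc:
        raise PEtabFormatError([f"YAML index is missing required entries: {exc}"])

    model = import_sbml(str(sbml_file))

    cond_df = _read_tsv(cond_file, "condition", ["conditionId"], errors)
    obs_df = _read_tsv(
        obs_file, "observable", ["observableId", "observableFormula"], errors
    )
    meas_df = _read_tsv(
        meas_file,
        "measurement",
        ["observableId", "simulationConditionId", "time", "measurement"],
        errors,
    )
    par_df = _read_tsv(
        par_file,
        "parameter",
        ["parameterId", "parameterScale", "nominalValue", "estimate"],
        errors,
    )
    if errors:
        raise PEtabFormatError(errors)

    # --- parameters ---------------------------------------------------------
    parameters = []
    for _, row in par_df.iterrows():
        scale = str(row["parameterScale"])
        if scale not in _SCALES:
            errors.append(
                f"parameter {row['parameterId']}: unknown scale {scale!r}"
            )
            scale = "lin"
        if not _is_number(row["nominalValue"]):
            errors.append(
                f"parameter {row['parameterId']}: non-numeric nominalValue "
                f"{row['nominalValue']!r}"
            )
            continue
        parameters.append(
            ParameterSpec(
                id=str(row["parameterId"]),
                nominal=float(row["nominalValue"]),
                scale=scale,
                lower=float(row.get("lowerBound", -math.inf))
                if "lowerBound" in par_df.columns and _is_number(row.get("lowerBound"))
                else -math.inf,
                upper=float(row.get("upperBound", math.inf))
                if "upperBound" in par_df.columns and _is_number(row.get("upperBound"))
                else math.inf,
                estimate=bool(int(row["estimate"])),
            )
        )
    par_ids = {p.id for p in parameters}
    if len(par_ids) != len(parameters):
        errors.append("duplicate parameterId entries in the parameter table")

    model_ids = (
        set(model.parameter_ids) | set(model.fixed_parameter_ids) | set(model.state_ids)
    )
    table_values = {p.id: p.nominal for p in parameters}

    # --- observables: resolve placeholder overrides into instances ----------
    obs_meta = {}
    for _, row in obs_df.iterrows():
        oid = str(row["observableId"])
        dist = str(row.get("noiseDistribution", "normal"))
        if isinstance(row.get("noiseDistribution"), float) and math.isnan(
            row.get("noiseDistribution")
        ):
            dist = "normal"
        trafo = str(row.get("observableTransformation", "lin"))
        if isinstance(row.get("observableTransformation"), float) and math.isnan(
            row.get("observableTransformation")
        ):
            trafo = "lin"
        if dist not in ("normal",):
            if dist == "laplace":
                errors.append(
                    f"observable {oid}: noiseDistribution 'laplace' is not supported "
                    "(only normal and log-normal likelihoods)"
                )
                dist = "normal"
            else:
                errors.append(f"observable {oid}: unknown noiseDistribution {dist!r}")
                dist = "normal"
        if trafo not in ("lin", "log"):
            errors.append(
                f"observable {oid}: observableTransformation {trafo!r} not supported"
            )
            trafo = "lin"
        noise_raw = row.get("noiseFormula", 1.0)
        if noise_raw is None or (isinstance(noise_raw, float) and math.isnan(noise_raw)):
            noise_raw = 1.0
        obs_meta[oid] = {
            "formula": _parse_formula(row["observableFormula"], f"observable {oid}", errors),
            "noise": _parse_formula(noise_raw, f"noise of {oid}", errors),
            "distribution": "lognormal" if trafo == "log" else "normal",
        }

    if meas_df is not None:
        unknown_obs = set(meas_df["observableId"].astype(str)) - set(obs_meta)
        for o in sorted(unknown_obs):
            errors.append(f"measurement references unknown observable {o!r}")

    def split_overrides(raw):
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return ()
        return tuple(s.strip() for s in str(raw).split(";") if s.strip())

    # distinct (observable, observableParameters, noiseParameters) combinations
    combos = []
    combo_index = {}
    for _, row in meas_df.iterrows():
        oid = str(row["observableId"])
        if oid not in obs_meta:
            continue
        key = (
            oid,
            split_overrides(row.get("observableParameters")),
            split_overrides(row.get("noiseParameters")),
        )
        if key not in combo_index:
            combo_index[key] = len(combos)
            combos.append(key)

    extra_params = []  # estimated/table parameters referenced but absent from model

    def resolve_token(tok, where):
        if _is_number(tok):
            return sp.Float(float(tok))
        if tok in model_ids:
            return sym(tok)
        if tok in par_ids:
            if tok not in {e for e in extra_params}:
                extra_params.append(tok)
            return sym(tok)
        errors.append(f"{where}: reference to unknown id {tok!r}")
        return sp.Integer(0)

    instances = {}   # instance id -> (formula, noise)
    instance_dist = []
    for idx, (oid, obs_over, noise_over) in enumerate(combos):
        meta = obs_meta[oid]
        formula, noise = meta["formula"], meta["noise"]
        subs = {}
        for i, tok in enumerate(obs_over, start=1):
            subs[sym(f"observableParameter{i}_{oid}")] = resolve_token(
                tok, f"observableParameters of {oid}"
            )
        for i, tok in enumerate(noise_over, start=1):
            subs[sym(f"noiseParameter{i}_{oid}")] = resolve_token(
                tok, f"noiseParameters of {oid}"
            )
        formula = formula.xreplace(subs)
        noise = noise.xreplace(subs)
        for expr, what in ((formula, "observable"), (noise, "noise")):
            for s in expr.free_symbols:
                if s.name not in model_ids and s.name not in par_ids:
                    if re.match(r"(observable|noise)Parameter\d+_", s.name):
                        errors.append(
                            f"{what} formula of {oid}: unfilled placeholder {s.name}"
                        )
                    else:
                        errors.append(
                            f"{what} formula of {oid}: unknown symbol {s.name}"
                        )
                elif s.name in par_ids and s.name not in model_ids:
                    if s.name not in extra_params:
                        extra_params.append(s.name)
        unique = sum(1 for c in combos if c[0] == oid) == 1
        iid = oid if unique else f"{oid}__c{idx}"
        instances[iid] = (formula, noise)
        instance_dist.append(meta["distribution"])

    # --- conditions ----------------------------------------------------------
    conditions = {}
    estimated_ids = [p.id for p in parameters if p.estimate]
    targets = [c for c in cond_df.columns if c not in ("conditionId", "conditionName")]
    for tgt in targets:
        if tgt not in model_ids:
            errors.append(f"condition table targets unknown model entity {tgt!r}")
        elif tgt in estimated_ids:
            errors.append(
                f"condition table overrides estimated parameter {tgt!r}; only fixed "
                "parameters and species initial values may be condition-specific"
            )
    for _, row in cond_df.iterrows():
        cid = str(row["conditionId"])
        overrides = {}
        for tgt in targets:
            val = row[tgt]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            if _is_number(val):
                overrides[tgt] = float(val)
            elif str(val) in par_ids:
                if str(val) in estimated_ids:
                    errors.append(
                        f"condition {cid}: override of {tgt} references estimated "
                        f"parameter {val!r} (not supported)"
                    )
                overrides[tgt] = str(val)
            else:
                errors.append(
                    f"condition {cid}: override value {val!r} for {tgt} is neither "
                    "numeric nor a parameter id"
                )
        conditions[cid] = Condition(id=cid, overrides=overrides)

    # --- measurements ---------------------------------------------------------
    measurements = []
    for _, row in meas_df.iterrows():
        oid = str(row["observableId"])
        if oid not in obs_meta:
            continue
        cid = str(row["simulationConditionId"])
        if cid not in conditions:
            errors.append(f"measurement references unknown condition {cid!r}")
            continue
        preeq = row.get("preequilibrationConditionId")
        if preeq is None or (isinstance(preeq, float) and math.isnan(preeq)):
            preeq = None
        else:
            preeq = str(preeq)
            if preeq not in conditions:
                errors.append(
                    f"measurement references unknown pre-equilibration condition {preeq!r}"
                )
                continue
        if not _is_number(row["time"]):
            errors.append(f"non-numeric measurement time {row['time']!r}")
            continue
        t = float(row["time"])
        if not math.isfinite(t) or t < 0:
            errors.append(
                f"measurement time {t!r} must be finite and >= 0 "
                "(steady-state measurements are not supported)"
            )
            continue
        if not _is_number(row["measurement"]):
            errors.append(f"non-numeric measurement value {row['measurement']!r}")
            continue
        key = (
            oid,
            split_overrides(row.get("observableParameters")),
            split_overrides(row.get("noiseParameters")),
        )
        idx = combo_index[key]
        measurements.append(
            MeasurementRow(
                condition_id=cid,
                preequilibration_condition_id=preeq,
                observable_instance=idx,
                time=t,
                value=float(row["measurement"]),
                distribution=instance_dist[idx],
            )
        )

    estimated_missing = [
        p.id
        for p in parameters
        if p.estimate and p.id not in model_ids and p.id not in extra_params
    ]
    for pid in estimated_missing:
        errors.append(
            f"estimated parameter {pid!r} does not appear in the model or any formula"
        )

    if errors:
        raise PEtabFormatError(sorted(set(errors)))

    # --- assemble the augmented model -----------------------------------------
    aug = model
    for pid in extra_params:
        aug = aug.add_parameter(pid, table_values[pid])
    aug = aug.with_observables(
        {iid: f for iid, (f, s) in instances.items()},
        {iid: s for iid, (f, s) in instances.items()},
    )
    # dynamic parameters := estimated parameters; everything else fixed
    aug = aug.repartition(estimated_ids)
    # non-estimated table parameters pin their nominal values onto k
    fixed_vals = dict(aug.fixed_parameter_values)
    for p in parameters:
        if not p.estimate and p.id in aug.fixed_parameter_ids:
            fixed_vals[p.id] = p.nominal
    aug.fixed_parameter_values = fixed_vals

    compiled = compile_model(aug)
    return EstimationProblem(
        model=aug,
        compiled=compiled,
        conditions=conditions,
        measurements=measurements,
        parameters=parameters,
        observable_meta=obs_meta,
    )


# ---------------------------------------------------------------------------
# condition mapping and the simulation pipeline
# ---------------------------------------------------------------------------


@dataclass
class AppliedCondition:
    p: np.ndarray      # dynamic parameters, linear scale
    k: np.ndarray      # fixed parameters after overrides
    x0: np.ndarray     # initial state after overrides
    sx0: np.ndarray    # d x0 / d p (overridden species rows are zero)


def apply_condition(problem: EstimationProblem, condition_id, p_est) -> AppliedCondition:
    """Numeric (p, k, x0) for one condition at estimation-scale parameters."""
    cond = problem.conditions[condition_id]
    model = problem.model
    cm = problem.compiled
    est = [p for p in problem.parameters if p.estimate]
    p_est = np.asarray(p_est, dtype=float)
    if p_est.shape != (len(est),):
        raise ValueError(f"expected {len(est)} estimated parameters, got {p_est.shape}")
    p_lin = np.array([from_scale(v, spec.scale) for v, spec in zip(p_est, est)])

    table_values = {pp.id: pp.nominal for pp in problem.parameters}

    def resolve(value):
        if isinstance(value, str):
            if value in table_values:
                return table_values[value]
            if value in model.fixed_parameter_values:
                return model.fixed_parameter_values[value]
            raise KeyError(f"unresolved override reference {value!r}")
        return float(value)

    k = model.nominal_fixed_parameters()
    k_index = {kid: i for i, kid in enumerate(model.fixed_parameter_ids)}
    state_index = {s: i for i, s in enumerate(model.state_ids)}
    species_over = {}
    for tgt, val in cond.overrides.items():
        if tgt in k_index:
            k[k_index[tgt]] = resolve(val)
        elif tgt in state_index:
            species_over[state_index[tgt]] = resolve(val)
        else:
            raise KeyError(f"override target {tgt!r} is neither fixed parameter nor state")

    x0 = cm.x0(p_lin, k)
    sx0 = cm.dx0dp(p_lin, k).toarray()
    for i, v in species_over.items():
        x0[i] = v
        sx0[i, :] = 0.0
    return AppliedCondition(p=p_lin, k=k, x0=x0, sx0=sx0)


def _pipeline_initial_state(problem, cond: Condition, applied: AppliedCondition,
                            p_est, cfg, want_sensitivities):
    """Resolve pre-equilibration and pre-simulation into (x0, sx0, preeq_info)."""
    x0, sx0 = applied.x0, applied.sx0
    preeq_applied = None
    if cond.preequilibration_condition_id is not None:
        preeq_applied = apply_condition(
            problem, cond.preequilibration_condition_id, p_est
        )
        try:
            ss = find_steady_state(
                problem.compiled, preeq_applied.p, preeq_applied.k,
                preeq_applied.x0, cfg
            )
        except OdesensError as exc:
            exc.args = (f"[preeq] {exc}",)
            raise
        x0 = ss.x_ss.copy()
        if want_sensitivities:
            sss = steadystate_sensitivities(
                problem.compiled, ss, preeq_applied.p, preeq_applied.k, cfg,
                x_init=preeq_applied.x0, sx_init=preeq_applied.sx0,
            )
            sx0 = sss.sx.copy()
        else:
            sx0 = None
        # species explicitly overridden by the main condition are reinitialised
        state_index = {s: i for i, s in enumerate(problem.model.state_ids)}
        for tgt, val in cond.overrides.items():
            if tgt in state_index:
                i = state_index[tgt]
                x0[i] = applied.x0[i]
                if sx0 is not None:
                    sx0[i, :] = applied.sx0[i, :]
    if cond.presimulation is not None:
        presim = cond.presimulation
        k_pre = applied.k.copy()
        k_index = {kid: i for i, kid in enumerate(problem.model.fixed_parameter_ids)}
        for tgt, val in presim.overrides.items():
            if tgt not in k_index:
                raise KeyError(
                    f"pre-simulation override target {tgt!r} is not a fixed parameter"
                )
            k_pre[k_index[tgt]] = float(val)
        tgrid = [0.0, float(presim.duration)]
        try:
            if want_sensitivities:
                fsr = forward_sensitivities(
                    problem.compiled, applied.p, k_pre, x0, tgrid, cfg,
                    sx_init=sx0,
                )
                x0 = fsr.trajectory.states[-1].copy()
                sx0 = fsr.sx[-1].copy()
            else:
                traj = simulate(problem.compiled, applied.p, k_pre, x0, tgrid, cfg)
                x0 = traj.states[-1].copy()
        except OdesensError as exc:
            exc.args = (f"[presim] {exc}",)
            raise
    return x0, sx0


def equilibrate_and_simulate(
    problem: EstimationProblem,
    condition_id,
    p_est,
    cfg: SolverConfig | None = None,
    want_sensitivities: bool = False,
    timepoints=None,
    preequilibration_condition_id=None,
):
    """Pre-equilibrate / pre-simulate / simulate one condition.

    Returns a :class:`Trajectory`, or a ``ForwardSensitivityResult`` when
    ``want_sensitivities`` is set. ``timepoints`` defaults to the sorted
    measurement times of the condition.
    """
    if cfg is None:
        cfg = SolverConfig()
    cond = problem.conditions[condition_id]
    if preequilibration_condition_id is not None:
        cond = Condition(
            id=cond.id,
            overrides=cond.overrides,
            preequilibration_condition_id=preequilibration_condition_id,
            presimulation=cond.presimulation,
        )
    applied = apply_condition(problem, condition_id, p_est)
    x0, sx0 = _pipeline_initial_state(
        problem, cond, applied, p_est, cfg, want_sensitivities
    )
    if timepoints is None:
        times = sorted(
            {m.time for m in problem.measurements if m.condition_id == condition_id}
        )
        timepoints = [0.0] + [t for t in times if t > 0.0] if times else [0.0]
        if times and times[0] == 0.0:
            pass
    try:
        if want_sensitivities:
            return forward_sensitivities(
                problem.compiled, applied.p, applied.k, x0, timepoints, cfg,
                sx_init=sx0,
            )
        return simulate(problem.compiled, applied.p, applied.k, x0, timepoints, cfg)
    except OdesensError as exc:
        exc.args = (f"[main] {exc}",)
        raise


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def negloglik(y_sim, measurements, noise, distributions="normal") -> float:
    """Total negative log-likelihood of simulated values against measurements.

    ``noise`` is a scalar or per-point array of σ; ``distributions`` a string
    or per-point list. Normal noise contributes
    0.5·((ȳ−y)/σ)² + 0.5·log(2πσ²) per point; log-normal applies the same to
    log-values plus log(ȳ).
    """
    y_sim = np.atleast_1d(np.asarray(y_sim, dtype=float))
    ybar = np.atleast_1d(np.asarray(measurements, dtype=float))
    if y_sim.shape != ybar.shape:
        raise ValueError("simulated and measured values must align one-to-one")
    sig = np.broadcast_to(np.atleast_1d(np.asarray(noise, dtype=float)), y_sim.shape)
    if isinstance(distributions, str):
        dists = [distributions] * len(y_sim)
    else:
        dists = list(distributions)
    total = 0.0
    for y, m, s, d in zip(y_sim, ybar, sig, dists):
        if np.isnan(y):
            raise ValueError("missing simulated value for a measurement")
        total += nll_point(float(y), float(s), float(m), d)[0]
    return float(total)


def _experiments(problem):
    """Deterministic grouping of measurements into simulation units.

    One unit per (condition, pre-equilibration) pair, sorted by key; rows
    inside a unit are sorted by (time, instance, value) so aggregation order
    never depends on table order.
    """
    groups = {}
    for m in problem.measurements:
        key = (m.condition_id, m.preequilibration_condition_id or "")
        groups.setdefault(key, []).append(m)
    for key in sorted(groups):
        rows = sorted(
            groups[key], key=lambda m: (m.time, m.observable_instance, m.value)
        )
        yield key, rows


def _condition_nll(problem, cid, preeq, rows, p_est, cfg) -> float:
    """NLL of one (condition, pre-equilibration) unit via plain simulation.

    This is the single code path that produces objective *values*, so the
    value is bit-identical no matter which sensitivity method runs alongside.
    """
    traj = equilibrate_and_simulate(
        problem, cid, p_est, cfg,
        timepoints=sorted({0.0} | {m.time for m in rows}),
        preequilibration_condition_id=preeq or None,
    )
    t_index = {t: i for i, t in enumerate(traj.timepoints)}
    applied = apply_condition(problem, cid, p_est)
    sigmas = problem.compiled.sigma(applied.p, applied.k)
    total = 0.0
    for m in rows:
        y = traj.outputs[t_index[m.time], m.observable_instance]
        total += nll_point(
            float(y), float(sigmas[m.observable_instance]), m.value, m.distribution
        )[0]
    return float(total)


def evaluate_objective(problem, p_est, cfg: SolverConfig | None = None) -> float:
    """Objective value only (no sensitivities); used by FD cross-checks."""
    if cfg is None:
        cfg = SolverConfig()
    total = 0.0
    for (cid, preeq), rows in _experiments(problem):
        total += _condition_nll(problem, cid, preeq, rows, p_est, cfg)
    return float(total)


def objective_and_gradient(
    problem: EstimationProblem,
    p_est,
    method: str = "forward",
    cfg: SolverConfig | None = None,
    on_failure: str = "error",
) -> GradientResult:
    """NLL value and gradient on the estimation scale, summed over conditions.

    Conditions are evaluated independently and aggregated in a fixed sorted
    order, so the result is bit-identical under any evaluation or row order.
    ``on_failure='inf'`` maps failing conditions to a +inf objective instead
    of raising.
    """
    if cfg is None:
        cfg = SolverConfig()
    if method not in ("forward", "adjoint"):
        raise ValueError(f"unknown sensitivity method {method!r}")
    p_est = np.asarray(p_est, dtype=float)
    est = [p for p in problem.parameters if p.estimate]
    total_value = 0.0
    total_grad = np.zeros(len(est))
    per_condition = {}
    failures = []

    for (cid, preeq), rows in _experiments(problem):
        cond = problem.conditions[cid]
        if method == "adjoint" and cond.presimulation is not None:
            raise NotSupportedError(
                "adjoint sensitivities are not supported together with "
                "pre-simulation (only with pre-equilibration)"
            )
        try:
            applied = apply_condition(problem, cid, p_est)
            eff_cond = Condition(
                id=cond.id,
                overrides=cond.overrides,
                preequilibration_condition_id=preeq or None,
                presimulation=cond.presimulation,
            )
            x0, sx0 = _pipeline_initial_state(
                problem, eff_cond, applied, p_est, cfg, want_sensitivities=True
            )
            datapoints = [
                DataPoint(
                    t=m.time,
                    observable_index=m.observable_instance,
                    value=m.value,
                    distribution=m.distribution,
                )
                for m in rows
            ]
            if method == "forward":
                res = forward_gradient(
                    problem.compiled, applied.p, applied.k, x0, datapoints, cfg,
                    sx_init=sx0,
                )
            else:
                res = adjoint_gradient(
                    problem.compiled, applied.p, applied.k, x0, datapoints, cfg,
                    sx0=sx0,
                )
            # the value goes through the shared plain-simulation path, so it
            # is bit-identical between the forward and adjoint methods
            value = _condition_nll(problem, cid, preeq, rows, p_est, cfg)
        except OdesensError as exc:
            failures.append((cid, exc))
            continue
        # chain rule onto the estimation scale
        factors = np.array(
            [scale_chain_factor(pl, spec.scale) for pl, spec in zip(applied.p, est)]
        )
        grad_scaled = res.gradient * factors
        total_value += value
        total_grad = total_grad + grad_scaled
        per_condition[(cid, preeq)] = {
            "value": value,
            "gradient": grad_scaled,
            "n_measurements": len(rows),
        }

    if failures:
        if on_failure == "inf":
            return GradientResult(
                value=math.inf,
                gradient=np.full(len(est), np.nan),
                method=method,
                per_condition=per_condition,
            )
        raise ObjectiveEvaluationError(failures)
    return GradientResult(
        value=total_value,
        gradient=total_grad,
        method=method,
        per_condition=per_condition,
    )
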