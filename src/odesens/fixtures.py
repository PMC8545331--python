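"""Fixture model catalogue with analytic references and PEtab bundles.

Each fixture exercises a distinct failure mode of the math core:

========================  ====================================================
decay                     linear, analytic solution and sensitivities
linear_chain(n)           lower-bidiagonal Jacobian, cascade analytics
conversion                conserved total, singular Jacobian at steady state
synthesis_degradation     nontrivial steady state, pre-equilibration phases
lotka_volterra            nonlinear, oscillatory, finite-difference oracles
========================  ====================================================

For every linear fixture the closed-form solution x(t) = e^{At} x0 (plus the
particular solution when a constant inflow is present) and its parameter
derivatives are built symbolically once and compiled; these are the
independent oracles the test-suite compares simulations against.

``generate_fixture`` writes the SBML file (and, on request, a complete PEtab
bundle with seeded synthetic measurements) so that import and estimation
round-trip through the public file formats.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sympy as sp

from .mathml import TIME_SYMBOL
from .model import Model, reactions_to_odes, sym
from .sbml import export_sbml

FIXTURE_NAMES = (
    "decay",
    "conversion",
    "synthesis_degradation",
    "lotka_volterra",
    "linear_chain",
)


@dataclass
class FixtureSpec:
    """Recipe for a fixture model and (optionally) its PEtab bundle."""

    name: str
    n: int = 4                      # chain length for linear_chain
    petab: bool = False
    estimate_noise: bool = False    # noise scale becomes an estimated parameter
    preequilibration: bool = False  # only meaningful for synthesis_degradation
    n_times: int = 10
    sigma: float = 0.02
    t_max: float = 3.0

    def __post_init__(self):
        if self.name not in FIXTURE_NAMES:
            raise ValueError(
                f"unknown fixture {self.name!r}; choose from {', '.join(FIXTURE_NAMES)}"
            )
        if self.name == "linear_chain" and self.n < 2:
            raise ValueError("linear_chain needs n >= 2")


@dataclass
class Fixture:
    spec: FixtureSpec
    model: Model
    p_true: np.ndarray            # true dynamic parameters (linear scale)
    analytic: object | None = None  # callable (t, p, k) -> (x, sx) or None


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _decay_model(estimate_noise=False):
    x1, k1 = sym("x1"), sym("k1")
    obs = {"obs_x1": x1}
    params = ["k1"]
    values = {"k1": 1.0}
    if estimate_noise:
        params.append("sigma_x1")
        values["sigma_x1"] = 0.05
        noise = {"obs_x1": sym("sigma_x1")}
    else:
        noise = {"obs_x1": sp.Float(0.05)}
    return Model(
        state_ids=["x1"],
        parameter_ids=params,
        fixed_parameter_ids=[],
        rhs=reactions_to_odes([[-1]], [k1 * x1]),
        initials=[sp.Float(1.0)],
        parameter_values=values,
        observables=obs,
        noise_formulas=noise,
        stoichiometry=[[-1]],
        fluxes=[k1 * x1],
        name="decay",
    )


def _conversion_model():
    A, B, k1, k2 = sym("A"), sym("B"), sym("k1"), sym("k2")
    S = [[-1, 1], [1, -1]]
    v = [k1 * A, k2 * B]
    return Model(
        state_ids=["A", "B"],
        parameter_ids=["k1", "k2"],
        fixed_parameter_ids=[],
        rhs=reactions_to_odes(S, v),
        initials=[sp.Float(1.0), sp.Float(0.0)],
        parameter_values={"k1": 1.0, "k2": 2.0},
        observables={"obs_a": A, "obs_b": B},
        noise_formulas={"obs_a": sp.Float(0.02), "obs_b": sp.Float(0.02)},
        stoichiometry=S,
        fluxes=v,
        name="conversion",
    )


def _synthesis_degradation_model():
    # synthesis rate a is condition-settable (fixed), degradation b dynamic
    x1, a, b = sym("x1"), sym("a"), sym("b")
    S = [[1, -1]]
    v = [a, b * x1]
    return Model(
        state_ids=["x1"],
        parameter_ids=["b"],
        fixed_parameter_ids=["a"],
        rhs=reactions_to_odes(S, v),
        initials=[sp.Float(0.0)],
        parameter_values={"b": 4.0},
        fixed_parameter_values={"a": 2.0},
        observables={"obs_x1": x1},
        noise_formulas={"obs_x1": sp.Float(0.01)},
        stoichiometry=S,
        fluxes=v,
        name="synthesis_degradation",
    )


def _lotka_volterra_model():
    prey, pred = sym("prey"), sym("predator")
    alpha, beta, delta, gamma = (sym(s) for s in ("alpha", "beta", "delta", "gamma"))
    # prey birth, predation loss, predator growth, predator death
    S = [[1, -1, 0, 0], [0, 0, 1, -1]]
    v = [alpha * prey, beta * prey * pred, delta * prey * pred, gamma * pred]
    return Model(
        state_ids=["prey", "predator"],
        parameter_ids=["alpha", "beta", "delta", "gamma"],
        fixed_parameter_ids=[],
        rhs=reactions_to_odes(S, v),
        initials=[sp.Float(1.0), sp.Float(1.0)],
        parameter_values={"alpha": 1.5, "beta": 1.0, "delta": 1.0, "gamma": 3.0},
        observables={"obs_prey": prey, "obs_predator": pred},
        noise_formulas={"obs_prey": sp.Float(0.05), "obs_predator": sp.Float(0.05)},
        stoichiometry=S,
        fluxes=v,
        name="lotka_volterra",
    )


def _linear_chain_model(n):
    states = [f"x{i + 1}" for i in range(n)]
    params = [f"k{i + 1}" for i in range(n)]
    xs = [sym(s) for s in states]
    ks = [sym(p) for p in params]
    # x1 -> x2 -> ... -> xn -> 0, first-order throughout
    S = [[0] * n for _ in range(n)]
    v = []
    for j in range(n):
        v.append(ks[j] * xs[j])
        S[j][j] = -1
        if j + 1 < n:
            S[j + 1][j] = 1
    # distinct rates keep the matrix exponential's eigenvalues simple
    values = {f"k{i + 1}": 1.0 + 0.4 * i for i in range(n)}
    return Model(
        state_ids=states,
        parameter_ids=params,
        fixed_parameter_ids=[],
        rhs=reactions_to_odes(S, v),
        initials=[sp.Float(1.0)] + [sp.Float(0.0)] * (n - 1),
        parameter_values=values,
        observables={"obs_last": xs[-1]},
        noise_formulas={"obs_last": sp.Float(0.02)},
        stoichiometry=S,
        fluxes=v,
        name=f"linear_chain{n}",
    )


def build_model(spec: FixtureSpec) -> Model:
    if spec.name == "decay":
        return _decay_model(estimate_noise=spec.estimate_noise)
    if spec.name == "conversion":
        return _conversion_model()
    if spec.name == "synthesis_degradation":
        return _synthesis_degradation_model()
    if spec.name == "lotka_volterra":
        return _lotka_volterra_model()
    if spec.name == "linear_chain":
        return _linear_chain_model(spec.n)
    raise ValueError(spec.name)


# ---------------------------------------------------------------------------
# analytic references for linear models
# ---------------------------------------------------------------------------


class LinearAnalytic:
    """Closed-form solution x(t) = e^{At}x0 (+ particular part) and ∂x/∂p.

    Built symbolically (matrix exponential, then differentiation w.r.t. every
    dynamic parameter) and compiled; completely independent of the numeric
    integrator it serves as an oracle for.
    """

    def __init__(self, model: Model):
        x = sp.Matrix(model.state_symbols)
        f = sp.Matrix(model.rhs)
        A = f.jacobian(x)
        b = sp.expand(f - A * x)
        if A.free_symbols & set(model.state_symbols):
            raise ValueError("model is not linear in the states")
        if b.free_symbols & set(model.state_symbols):
            raise ValueError("model is not affine in the states")
        t = TIME_SYMBOL
        x0 = sp.Matrix(model.initials)
        eAt = sp.simplify((A * t).exp())
        if b.is_zero_matrix:
            xt = eAt * x0
        else:
            Ainv_b = A.solve(b)
            xt = eAt * (x0 + Ainv_b) - Ainv_b
        xt = sp.Matrix([sp.expand(e) for e in xt])
        p = model.parameter_symbols
        sxt = xt.jacobian(sp.Matrix(p)) if p else sp.zeros(len(x0), 0)
        args = [t, *p, *model.fixed_parameter_symbols]
        self._n = len(x0)
        self._np = len(p)
        self._fx = sp.lambdify(args, list(xt), modules="numpy")
        self._fs = sp.lambdify(
            args, [sxt[i, j] for i in range(self._n) for j in range(self._np)],
            modules="numpy",
        )
        self.x_expr = xt
        self.sx_expr = sxt

    def __call__(self, t, p, k=()):
        vals = (float(t), *np.asarray(p, float), *np.asarray(k, float))
        x = np.asarray(self._fx(*vals), dtype=float).reshape(self._n)
        sx = np.asarray(self._fs(*vals), dtype=float).reshape(self._n, self._np)
        return x, sx


@functools.lru_cache(maxsize=None)
def _analytic_cached(name, n):
    spec = FixtureSpec(name=name, n=n)
    model = build_model(spec)
    try:
        return LinearAnalytic(model)
    except ValueError:
        return None


def get_fixture(name, n=4, **kwargs) -> Fixture:
    """Build a fixture by name, with its analytic reference where one exists."""
    spec = FixtureSpec(name=name, n=n, **kwargs)
    model = build_model(spec)
    return Fixture(
        spec=spec,
        model=model,
        p_true=model.nominal_parameters(),
        analytic=_analytic_cached(name, n),
    )


# ---------------------------------------------------------------------------
# file generation (SBML + PEtab bundles with seeded synthetic data)
# ---------------------------------------------------------------------------


def _fmt(x):
    return repr(float(x))


def _write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _simulate_true(model, timepoints):
    """High-accuracy reference simulation used for data generation."""
    from .codegen import compile_model
    from .solver import SolverConfig, simulate

    cm = compile_model(model)
    p = model.nominal_parameters()
    k = model.nominal_fixed_parameters()
    x0 = cm.x0(p, k)
    cfg = SolverConfig(rtol=1e-10, atol=1e-14)
    return cm, simulate(cm, p, k, x0, timepoints, cfg)


def generate_fixture(spec: FixtureSpec, seed: int, outdir) -> dict:
    """Write the fixture's SBML file (and PEtab bundle if requested).

    Measurement tables are a deterministic function of ``seed``: the same
    seed yields byte-identical files. Returns a dict of written paths; the
    PEtab YAML is under key ``"yaml"``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(spec)
    sbml_path = outdir / f"{model.name}.xml"
    sbml_path.write_text(export_sbml(model))
    paths = {"sbml": sbml_path}
    if not spec.petab:
        return paths

    rng = np.random.default_rng(seed)
    preeq = spec.preequilibration and spec.name == "synthesis_degradation"
    times = np.round(np.linspace(spec.t_max / spec.n_times, spec.t_max, spec.n_times), 6)
    sim_times = [0.0] + list(times)

    if preeq:
        # data generated from the equilibrated state under the main condition
        a_pre, a_main = 2.0, 0.0
        work = Model(
            **{**model.__dict__, "fixed_parameter_values": {"a": a_main}}
        )
        b = model.parameter_values["b"]
        work.initials = [sp.Float(a_pre / b)]
        cm, traj = _simulate_true(work, sim_times)
    else:
        cm, traj = _simulate_true(model, sim_times)

    obs_ids = model.observable_ids
    noise_value = spec.sigma

    meas_rows = []
    for ti, t in enumerate(times, start=1):
        for oi, oid in enumerate(obs_ids):
            y = traj.outputs[ti, oi]
            noisy = y + noise_value * rng.standard_normal()
            row = [oid, "main", _fmt(t), _fmt(noisy)]
            if preeq:
                row.insert(2, "preeq")
            meas_rows.append(row)

    meas_header = ["observableId", "simulationConditionId", "time", "measurement"]
    if preeq:
        meas_header = [
            "observableId",
            "simulationConditionId",
            "preequilibrationConditionId",
            "time",
            "measurement",
        ]
    meas_path = outdir / "measurements.tsv"
    _write_tsv(meas_path, meas_header, meas_rows)

    obs_rows = []
    for oid in obs_ids:
        formula = str(model.observables[oid])
        if spec.estimate_noise:
            noise = str(model.noise_formulas[oid])
        else:
            noise = _fmt(noise_value)
        obs_rows.append([oid, formula, noise])
    obs_path = outdir / "observables.tsv"
    _write_tsv(obs_path, ["observableId", "observableFormula", "noiseFormula"], obs_rows)

    if preeq:
        cond_path = outdir / "conditions.tsv"
        _write_tsv(cond_path, ["conditionId", "a"], [["preeq", _fmt(2.0)], ["main", _fmt(0.0)]])
    else:
        cond_path = outdir / "conditions.tsv"
        _write_tsv(cond_path, ["conditionId"], [["main"]])

    par_rows = []
    for pid in model.parameter_ids:
        nominal = model.parameter_values[pid]
        par_rows.append(
            [pid, "log10", _fmt(1e-3), _fmt(1e3), _fmt(nominal), "1"]
        )
    par_path = outdir / "parameters.tsv"
    _write_tsv(
        par_path,
        ["parameterId", "parameterScale", "lowerBound", "upperBound", "nominalValue", "estimate"],
        par_rows,
    )

    yaml_path = outdir / "problem.yaml"
    yaml_path.write_text(
        "format_version: 1\n"
        f"parameter_file: {par_path.name}\n"
        "problems:\n"
        f"  - sbml_files: [{sbml_path.name}]\n"
        f"    condition_files: [{cond_path.name}]\n"
        f"    measurement_files: [{meas_path.name}]\n"
        f"    observable_files: [{obs_path.name}]\n"
    )
    paths.update(
        {
            "yaml": yaml_path,
            "measurements": meas_path,
            "observables": obs_path,
            "conditions": cond_path,
            "parameters": par_path,
        }
    )
    return paths
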