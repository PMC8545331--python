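"""Symbolic intermediate representation of an ODE reaction-network model.

A :class:`Model` holds the system

    dx/dt = f(x, p, k, t),   x(t0) = x0(p, k),
    y     = h(x, p, k),      sigma = sigma(p, k),

where ``x`` are state variables (species concentrations), ``p`` dynamic
parameters (the ones sensitivities are taken with respect to), ``k`` fixed,
condition-settable constants (including compartment sizes), ``y`` observables
and ``sigma`` their noise scales. For models built from reactions the
right-hand side is assembled as the stoichiometric matrix times the flux
vector, f = S·v.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import sympy as sp

from .mathml import TIME_SYMBOL


def sym(name: str) -> sp.Symbol:
    """The canonical real-valued symbol used throughout odesens."""
    return sp.Symbol(name, real=True)


@dataclass
class ImportDiagnostics:
    """Outcome of an SBML import attempt.

    ``unsupported_features`` is a list of ``(construct, location, message)``
    triples; a non-empty list aborts the import.
    """

    unsupported_features: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_unsupported(self, construct, location, message):
        self.unsupported_features.append((construct, location, message))

    @property
    def ok(self):
        return not self.unsupported_features


@dataclass
class Model:
    """Symbolic ODE model; see module docstring for the naming convention."""

    state_ids: list
    parameter_ids: list          # dynamic parameters p
    fixed_parameter_ids: list    # condition-settable constants k
    rhs: list                    # f(x, p, k, t), one sympy expression per state
    initials: list               # x0(p, k), one expression per state
    parameter_values: dict = field(default_factory=dict)        # nominal p
    fixed_parameter_values: dict = field(default_factory=dict)  # nominal k
    observables: dict = field(default_factory=dict)             # id -> h(x,p,k)
    noise_formulas: dict = field(default_factory=dict)          # id -> sigma(p,k)
    stoichiometry: list | None = None   # integer matrix, species x reactions
    fluxes: list | None = None          # kinetic laws v(x,p,k,t)
    name: str = "model"

    # -- convenience views --------------------------------------------------

    @property
    def n_states(self):
        return len(self.state_ids)

    @property
    def n_parameters(self):
        return len(self.parameter_ids)

    @property
    def n_fixed_parameters(self):
        return len(self.fixed_parameter_ids)

    @property
    def n_observables(self):
        return len(self.observables)

    @property
    def observable_ids(self):
        return list(self.observables)

    @property
    def state_symbols(self):
        return [sym(s) for s in self.state_ids]

    @property
    def parameter_symbols(self):
        return [sym(s) for s in self.parameter_ids]

    @property
    def fixed_parameter_symbols(self):
        return [sym(s) for s in self.fixed_parameter_ids]

    def nominal_parameters(self):
        import numpy as np

        return np.array(
            [float(self.parameter_values.get(i, float("nan"))) for i in self.parameter_ids]
        )

    def nominal_fixed_parameters(self):
        import numpy as np

        return np.array(
            [
                float(self.fixed_parameter_values.get(i, float("nan")))
                for i in self.fixed_parameter_ids
            ]
        )

    # -- structure manipulation ---------------------------------------------

    def repartition(self, dynamic_ids) -> "Model":
        """Return a copy with a new dynamic/fixed split of the parameters.

        ``dynamic_ids`` become ``p`` (order preserved as given); every other
        current parameter (dynamic or fixed) becomes ``k``. Identifiers not
        known to the model raise ``KeyError``.
        """
        all_values = {**self.fixed_parameter_values, **self.parameter_values}
        known = set(self.parameter_ids) | set(self.fixed_parameter_ids)
        for pid in dynamic_ids:
            if pid not in known:
                raise KeyError(f"unknown parameter {pid!r}")
        dynamic = list(dynamic_ids)
        fixed = [i for i in self.parameter_ids + self.fixed_parameter_ids if i not in set(dynamic)]
        return replace(
            self,
            parameter_ids=dynamic,
            fixed_parameter_ids=fixed,
            parameter_values={i: all_values[i] for i in dynamic if i in all_values},
            fixed_parameter_values={i: all_values[i] for i in fixed if i in all_values},
        )

    def add_parameter(self, pid, value) -> "Model":
        """Return a copy with an extra dynamic parameter (used by PEtab loading)."""
        if pid in self.parameter_ids or pid in self.fixed_parameter_ids:
            raise ValueError(f"parameter {pid!r} already declared")
        return replace(
            self,
            parameter_ids=self.parameter_ids + [pid],
            parameter_values={**self.parameter_values, pid: value},
        )

    def with_observables(self, observables, noise_formulas) -> "Model":
        return replace(
            self, observables=dict(observables), noise_formulas=dict(noise_formulas)
        )


def reactions_to_odes(stoichiometry, fluxes):
    """Assemble the right-hand side f with f_i = sum_j S_ij * v_j.

    Sums are flattened (``sympy.Add``) but not otherwise simplified, so the
    reaction structure stays readable in the result.
    """
    n_reactions = len(fluxes)
    rhs = []
    for row in stoichiometry:
        if len(row) != n_reactions:
            raise ValueError(
                f"stoichiometry has {len(row)} columns but there are "
                f"{n_reactions} fluxes"
            )
        terms = [sp.Integer(c) * v for c, v in zip(row, fluxes) if c != 0]
        rhs.append(sp.Add(*terms) if terms else sp.Integer(0))
    return rhs


def validate_model(model: Model):
    """Structural diagnostics for a model; an empty list means valid.

    Checks identifier uniqueness/disjointness, that every free symbol in the
    equations is declared exactly once among {x, p, k, t}, and that rhs and
    state counts agree.
    """
    diags = []
    ids = (
        list(model.state_ids)
        + list(model.parameter_ids)
        + list(model.fixed_parameter_ids)
    )
    seen = set()
    for i in ids:
        if i in seen:
            diags.append(f"duplicate identifier {i!r}")
        seen.add(i)
    for oid in model.observables:
        if oid in seen:
            diags.append(f"observable id {oid!r} collides with a model identifier")
    if "t" in seen:
        diags.append("identifier 't' shadows the reserved time symbol")

    if len(model.rhs) != model.n_states:
        diags.append(
            f"rhs has {len(model.rhs)} entries for {model.n_states} states"
        )
    if len(model.initials) != model.n_states:
        diags.append(
            f"initials has {len(model.initials)} entries for {model.n_states} states"
        )

    declared = {sym(i) for i in ids} | {TIME_SYMBOL}

    def check(expr, where, allowed):
        for s in sp.sympify(expr).free_symbols:
            if s not in allowed:
                diags.append(f"undeclared symbol {s} in {where}")

    for i, expr in enumerate(model.rhs):
        check(expr, f"rhs[{i}]", declared)
    state_syms = {sym(i) for i in model.state_ids}
    no_states = declared - state_syms - {TIME_SYMBOL}
    for i, expr in enumerate(model.initials):
        check(expr, f"x0[{i}]", no_states)
    for oid, expr in model.observables.items():
        check(expr, f"observable {oid!r}", declared - {TIME_SYMBOL})
    for oid, expr in model.noise_formulas.items():
        # noise may depend on parameters only, never on states
        for s in sp.sympify(expr).free_symbols:
            if s in state_syms:
                diags.append(
                    f"noise formula for {oid!r} depends on state {s} "
                    "(state-dependent noise is not supported)"
                )
            elif s not in no_states:
                diags.append(f"undeclared symbol {s} in noise formula for {oid!r}")

    if model.stoichiometry is not None and model.fluxes is not None:
        assembled = reactions_to_odes(model.stoichiometry, model.fluxes)
        for i, (a, b) in enumerate(zip(assembled, model.rhs)):
            if sp.simplify(a - b) != 0:
                diags.append(f"rhs[{i}] does not equal (S·v)[{i}]")
    return diags
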