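"""SBML import (Level 3 core subset, plus L2V4+) and a subset writer.

Supported constructs: species, constant-size compartments, global and local
parameters, reactions with kinetic laws, assignment rules (substituted
symbolically), rate rules, initial assignments and function definitions
(expanded inline). Events, delay terms, algebraic rules, ``fast`` reactions
and non-constant compartments are rejected with diagnostics that name the
construct. Unit annotations are ignored: all values are taken at face value.

Species are represented internally as concentrations; species declared via
``initialAmount`` are divided by their compartment size at import.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import sympy as sp

from .exceptions import MalformedDocumentError, UnsupportedFeatureError
from .mathml import MATHML_NS, MathMLError, TIME_SYMBOL, parse_mathml, wrap_math
from .model import ImportDiagnostics, Model, reactions_to_odes, sym

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _local(tag):
    return tag.split("}", 1)[1] if tag.startswith("{") else tag


def _children(elem, name):
    return [c for c in elem if _local(c.tag) == name]


def _child(elem, name):
    found = _children(elem, name)
    return found[0] if found else None


def _math_child(elem):
    for c in elem:
        if _local(c.tag) == "math":
            return c
    return None


def _get_bool(elem, attr, default=False):
    raw = elem.get(attr)
    if raw is None:
        return default
    return raw in ("true", "1")


def import_sbml(document: str) -> Model:
    """Build a :class:`Model` from SBML text or a path to an SBML file.

    Raises :class:`MalformedDocumentError` for structural problems and
    :class:`UnsupportedFeatureError` (carrying :class:`ImportDiagnostics`)
    when the document uses constructs outside the ODE subset.
    """
    if os.path.exists(document) or (
        len(document) < 4096 and document.lstrip()[:1] != "<"
    ):
        try:
            with open(document) as fh:
                document = fh.read()
        except OSError as exc:
            raise MalformedDocumentError(f"cannot read {document!r}: {exc}") from exc

    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise MalformedDocumentError(f"not well-formed XML: {exc}") from exc

    if _local(root.tag) != "sbml":
        raise MalformedDocumentError(f"root element is <{_local(root.tag)}>, not <sbml>")
    level = int(root.get("level", "0"))
    version = int(root.get("version", "0"))
    if not (level == 3 or (level == 2 and version >= 4)):
        raise MalformedDocumentError(
            f"SBML Level {level} Version {version} is not supported "
            "(need Level 3 or Level 2 Version >= 4)"
        )
    model_elem = _child(root, "model")
    if model_elem is None:
        raise MalformedDocumentError("document has no <model> element")

    diags = ImportDiagnostics()

    def parse_math(elem, where):
        try:
            return parse_mathml(elem)
        except MathMLError as exc:
            diags.add_unsupported(exc.construct or "math", where, str(exc))
            return sp.Integer(0)

    # --- hard rejections ---------------------------------------------------
    for ev in _children(_child(model_elem, "listOfEvents") or (), "event"):
        diags.add_unsupported("event", ev.get("id", "<anonymous>"), "events are not supported")
    for cons in _children(_child(model_elem, "listOfConstraints") or (), "constraint"):
        diags.add_unsupported("constraint", "<constraint>", "constraints are not supported")

    # --- function definitions (expanded inline) ----------------------------
    funcdefs = {}
    for fd in _children(_child(model_elem, "listOfFunctionDefinitions") or (), "functionDefinition"):
        fid = fd.get("id")
        math = _math_child(fd)
        lam = parse_math(math, f"functionDefinition {fid}")
        if isinstance(lam, sp.Lambda):
            funcdefs[fid] = lam
        else:
            diags.add_unsupported(
                "functionDefinition", fid, "function definition body is not a lambda"
            )

    def expand_functions(expr):
        # substitute user-defined function applications, innermost first
        for _ in range(32):
            calls = [
                a for a in expr.atoms(sp.Function)
                if type(a).__name__ in funcdefs
            ]
            if not calls:
                break
            subs = {}
            for call in calls:
                lam = funcdefs[type(call).__name__]
                subs[call] = lam(*call.args)
            expr = expr.xreplace(subs)
        leftovers = {
            type(a).__name__
            for a in expr.atoms(sp.Function)
            if not isinstance(a, sp.Lambda) and a.atoms(sp.Symbol)
            and type(a).__name__ not in dir(sp)
        }
        for name in sorted(leftovers):
            diags.add_unsupported("functionCall", name, f"call to undefined function {name!r}")
        return expr

    # --- compartments -------------------------------------------------------
    compartments = {}
    for comp in _children(_child(model_elem, "listOfCompartments") or (), "compartment"):
        cid = comp.get("id")
        if not _get_bool(comp, "constant", default=True):
            diags.add_unsupported(
                "compartment", cid, "non-constant compartments are not supported"
            )
        size = comp.get("size", comp.get("volume"))
        compartments[cid] = float(size) if size is not None else 1.0

    # --- species ------------------------------------------------------------
    species_order = []
    species = {}
    for s in _children(_child(model_elem, "listOfSpecies") or (), "species"):
        sid = s.get("id")
        comp = s.get("compartment")
        conc = s.get("initialConcentration")
        amt = s.get("initialAmount")
        if conc is not None:
            init = sp.Float(conc)
        elif amt is not None:
            vol = compartments.get(comp, 1.0)
            init = sp.Float(float(amt) / vol)
        else:
            init = sp.Float(0.0)
        species[sid] = {
            "compartment": comp,
            "initial": init,
            "boundary": _get_bool(s, "boundaryCondition"),
            "constant": _get_bool(s, "constant"),
        }
        species_order.append(sid)

    # --- parameters ---------------------------------------------------------
    param_order = []
    params = {}
    for prm in _children(_child(model_elem, "listOfParameters") or (), "parameter"):
        pid = prm.get("id")
        val = prm.get("value")
        params[pid] = {
            "value": float(val) if val is not None else float("nan"),
            "constant": _get_bool(prm, "constant", default=(level == 2)),
        }
        param_order.append(pid)

    # --- rules --------------------------------------------------------------
    assignment_rules = {}
    rate_rules = {}
    for rule in _child(model_elem, "listOfRules") or ():
        tag = _local(rule.tag)
        var = rule.get("variable", "<unknown>")
        if tag == "algebraicRule":
            diags.add_unsupported("algebraicRule", var, "algebraic rules are not supported")
            continue
        math = expand_functions(parse_math(_math_child(rule), f"rule for {var}"))
        if tag == "assignmentRule":
            assignment_rules[var] = math
        elif tag == "rateRule":
            rate_rules[var] = math
        else:
            diags.add_unsupported(tag, var, f"rule type {tag!r} is not supported")

    # --- initial assignments ------------------------------------------------
    initial_assignments = {}
    for ia in _children(_child(model_elem, "listOfInitialAssignments") or (), "initialAssignment"):
        var = ia.get("symbol")
        initial_assignments[var] = expand_functions(
            parse_math(_math_child(ia), f"initialAssignment for {var}")
        )

    # --- reactions ----------------------------------------------------------
    reaction_ids = []
    fluxes = []
    stoich_map = []  # list of dicts species -> coefficient
    for rxn in _children(_child(model_elem, "listOfReactions") or (), "reaction"):
        rid = rxn.get("id")
        if _get_bool(rxn, "fast"):
            diags.add_unsupported("fast", rid, "'fast' reactions are not supported")
        kl = _child(rxn, "kineticLaw")
        if kl is None:
            diags.add_unsupported("reaction", rid, "reaction without a kinetic law")
            continue
        law = parse_math(_math_child(kl), f"kineticLaw of {rid}")
        # local parameters: renamed to globally unique ids
        locals_list = _child(kl, "listOfLocalParameters") or _child(kl, "listOfParameters")
        if locals_list is not None:
            ren = {}
            for lp in locals_list:
                lpid = lp.get("id")
                gid = f"{rid}_{lpid}"
                while gid in params or gid in species:
                    gid = gid + "_"
                params[gid] = {"value": float(lp.get("value", "nan")), "constant": True}
                param_order.append(gid)
                ren[sym(lpid)] = sym(gid)
            law = law.xreplace(ren)
        law = expand_functions(law)
        coeffs = {}
        for role, sign in (("listOfReactants", -1), ("listOfProducts", +1)):
            for ref in _children(_child(rxn, role) or (), "speciesReference"):
                spid = ref.get("species")
                st = float(ref.get("stoichiometry", "1"))
                if st != int(st):
                    diags.add_unsupported(
                        "stoichiometry", rid, f"non-integer stoichiometry {st} for {spid}"
                    )
                coeffs[spid] = coeffs.get(spid, 0) + sign * int(st)
        reaction_ids.append(rid)
        fluxes.append(law)
        stoich_map.append(coeffs)

    if not diags.ok:
        raise UnsupportedFeatureError(diags)

    # --- assemble the ODE system -------------------------------------------
    # assignment-rule targets are pure aliases: substituted everywhere, never states
    def resolve_assignments(expr, depth=0):
        if depth > 32:
            raise MalformedDocumentError("cyclic assignment rules")
        subs = {sym(v): e for v, e in assignment_rules.items()}
        new = sp.sympify(expr).xreplace(subs)
        if any(sym(v) in new.free_symbols for v in assignment_rules):
            return resolve_assignments(new, depth + 1)
        return new

    state_ids = [
        s
        for s in species_order
        if not species[s]["constant"] and s not in assignment_rules
    ]
    # parameters governed by a rate rule become states
    rate_param_states = [v for v in rate_rules if v in params]
    constant_species = [
        s for s in species_order if species[s]["constant"] or s in assignment_rules
    ]

    stoich = []
    pure_reaction_network = bool(reaction_ids) and not rate_rules
    for spid in state_ids:
        row = []
        for coeffs in stoich_map:
            c = coeffs.get(spid, 0)
            if species[spid]["boundary"]:
                c = 0  # boundary species: zero row in S
            row.append(c)
        stoich.append(row)

    rhs = []
    for i, spid in enumerate(state_ids):
        if spid in rate_rules:
            expr = rate_rules[spid]
        else:
            expr = reactions_to_odes([stoich[i]], fluxes)[0] if fluxes else sp.Integer(0)
            vol = compartments.get(species[spid]["compartment"], 1.0)
            if vol != 1.0:
                # SBML kinetic laws are amount rates; states are concentrations
                expr = expr / sym(species[spid]["compartment"])
                pure_reaction_network = False
        rhs.append(resolve_assignments(expr))
    for v in rate_param_states:
        rhs.append(resolve_assignments(rate_rules[v]))

    all_state_ids = state_ids + rate_param_states
    if rate_param_states:
        stoich = [row for row in stoich] + [[0] * len(fluxes) for _ in rate_param_states]

    initials = []
    for spid in state_ids:
        if spid in initial_assignments:
            init = initial_assignments[spid]
        else:
            init = species[spid]["initial"]
        initials.append(resolve_assignments(init))
    for v in rate_param_states:
        init = initial_assignments.get(v, sp.Float(params[v]["value"]))
        initials.append(resolve_assignments(init))

    # --- classify remaining symbols as p (dynamic) or k (fixed) -------------
    fixed_ids, dynamic_ids = [], []
    fixed_values, dynamic_values = {}, {}
    for pid in param_order:
        if pid in rate_param_states or pid in assignment_rules:
            continue
        if params[pid]["constant"]:
            fixed_ids.append(pid)
            fixed_values[pid] = params[pid]["value"]
        else:
            dynamic_ids.append(pid)
            dynamic_values[pid] = params[pid]["value"]
    for cid, size in compartments.items():
        fixed_ids.append(cid)
        fixed_values[cid] = size
    for spid in constant_species:
        if species[spid]["constant"]:
            fixed_ids.append(spid)
            fixed_values[spid] = float(resolve_assignments(species[spid]["initial"]))

    model = Model(
        state_ids=all_state_ids,
        parameter_ids=dynamic_ids,
        fixed_parameter_ids=fixed_ids,
        rhs=rhs,
        initials=initials,
        parameter_values=dynamic_values,
        fixed_parameter_values=fixed_values,
        stoichiometry=stoich if pure_reaction_network else None,
        fluxes=[resolve_assignments(v) for v in fluxes] if pure_reaction_network else None,
        name=model_elem.get("id", "model"),
    )

    # symbols referenced but never declared anywhere are an import error
    declared = (
        {sym(i) for i in model.state_ids}
        | {sym(i) for i in model.parameter_ids}
        | {sym(i) for i in model.fixed_parameter_ids}
        | {TIME_SYMBOL}
    )
    for i, expr in enumerate(model.rhs):
        for s in expr.free_symbols - declared:
            diags.add_unsupported("symbol", all_state_ids[i], f"undeclared symbol {s}")
    if not diags.ok:
        raise UnsupportedFeatureError(diags)
    return model


# ---------------------------------------------------------------------------
# writer (test helper; supported subset only, emitted as L3V2)
# ---------------------------------------------------------------------------


def export_sbml(model: Model, compartment_id: str = "default") -> str:
    """Serialise a model to SBML L3V2 text.

    Only the supported subset is written. Reaction structure is preserved when
    the model carries stoichiometry and fluxes; otherwise each state's rhs is
    written as a rate rule. All species live in one unit compartment.
    """
    ET.register_namespace("", SBML_L3_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(
        f"{{{SBML_L3_NS}}}sbml", {"level": "3", "version": "2"}
    )
    melem = ET.SubElement(root, f"{{{SBML_L3_NS}}}model", {"id": model.name})

    lst = ET.SubElement(melem, f"{{{SBML_L3_NS}}}listOfCompartments")
    ET.SubElement(
        lst,
        f"{{{SBML_L3_NS}}}compartment",
        {"id": compartment_id, "size": "1", "constant": "true"},
    )

    lst = ET.SubElement(melem, f"{{{SBML_L3_NS}}}listOfSpecies")
    numeric_inits = {}
    init_assignments = {}
    for sid, init in zip(model.state_ids, model.initials):
        e = sp.sympify(init)
        if e.is_Number:
            numeric_inits[sid] = float(e)
        else:
            numeric_inits[sid] = 0.0
            init_assignments[sid] = e
        ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}species",
            {
                "id": sid,
                "compartment": compartment_id,
                "initialConcentration": repr(numeric_inits[sid]),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    lst = ET.SubElement(melem, f"{{{SBML_L3_NS}}}listOfParameters")
    for pid in model.parameter_ids:
        ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}parameter",
            {
                "id": pid,
                "value": repr(float(model.parameter_values.get(pid, 0.0))),
                "constant": "false",
            },
        )
    for kid in model.fixed_parameter_ids:
        ET.SubElement(
            lst,
            f"{{{SBML_L3_NS}}}parameter",
            {
                "id": kid,
                "value": repr(float(model.fixed_parameter_values.get(kid, 0.0))),
                "constant": "true",
            },
        )

    if init_assignments:
        lst = ET.SubElement(melem, f"{{{SBML_L3_NS}}}listOfInitialAssignments")
        for sid, expr in init_assignments.items():
            ia = ET.SubElement(
                lst, f"{{{SBML_L3_NS}}}initialAssignment", {"symbol": sid}
            )
            ia.append(wrap_math(expr))

    if model.stoichiometry is not None and model.fluxes is not None:
        lst = ET.SubElement(melem, f"{{{SBML_L3_NS}}}listOfReactions")
        for j, flux in enumerate(model.fluxes):
            rxn = ET.SubElement(
                lst,
                f"{{{SBML_L3_NS}}}reaction",
                {"id": f"r{j}", "reversible": "false"},
            )
            reactants = ET.SubElement(rxn, f"{{{SBML_L3_NS}}}listOfReactants")
            products = ET.SubElement(rxn, f"{{{SBML_L3_NS}}}listOfProducts")
            for i, sid in enumerate(model.state_ids):
                c = model.stoichiometry[i][j]
                if c < 0:
                    ET.SubElement(
                        reactants,
                        f"{{{SBML_L3_NS}}}speciesReference",
                        {"species": sid, "stoichiometry": str(-c), "constant": "true"},
                    )
                elif c > 0:
                    ET.SubElement(
                        products,
                        f"{{{SBML_L3_NS}}}speciesReference",
                        {"species": sid, "stoichiometry": str(c), "constant": "true"},
                    )
            kl = ET.SubElement(rxn, f"{{{SBML_L3_NS}}}kineticLaw")
            kl.append(wrap_math(flux))
    else:
        lst = ET.SubElement(melem, f"{{{SBML_L3_NS}}}listOfRules")
        for sid, expr in zip(model.state_ids, model.rhs):
            rule = ET.SubElement(
                lst, f"{{{SBML_L3_NS}}}rateRule", {"variable": sid}
            )
            rule.append(wrap_math(expr))

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
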