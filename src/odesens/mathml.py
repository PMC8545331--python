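"""Content-MathML <-> sympy conversion for the SBML ODE subset.

SBML embeds kinetic laws and rule formulas as content MathML. Only the
constructs meaningful for smooth ODE right-hand sides are supported here;
``delay`` csymbols and unknown elements raise with the construct's name so
the importer can report them.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import sympy as sp

MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: reserved simulation-time symbol; models may reference it (non-autonomous rhs)
TIME_SYMBOL = sp.Symbol("t", real=True)

_TIME_URLS = {
    "http://www.sbml.org/sbml/symbols/time",
}
_AVOGADRO_URLS = {
    "http://www.sbml.org/sbml/symbols/avogadro",
}
_DELAY_URLS = {
    "http://www.sbml.org/sbml/symbols/delay",
}

_AVOGADRO = sp.Float("6.02214179e23")


class MathMLError(ValueError):
    """Raised for malformed or out-of-subset MathML; ``construct`` names the offender."""

    def __init__(self, message, construct=None):
        super().__init__(message)
        self.construct = construct


def _tag(elem):
    t = elem.tag
    if t.startswith("{"):
        return t.split("}", 1)[1]
    return t


def _symbol(name):
    return sp.Symbol(name, real=True)


# n-ary / unary / binary operator dispatch for <apply>
_NARY = {
    "plus": lambda args: sp.Add(*args) if args else sp.Integer(0),
    "times": lambda args: sp.Mul(*args) if args else sp.Integer(1),
    "and": lambda args: sp.And(*args),
    "or": lambda args: sp.Or(*args),
}

_UNARY_FUNCS = {
    "exp": sp.exp,
    "ln": sp.log,
    "abs": sp.Abs,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "arcsin": sp.asin,
    "arccos": sp.acos,
    "arctan": sp.atan,
    "sinh": sp.sinh,
    "cosh": sp.cosh,
    "tanh": sp.tanh,
    "not": sp.Not,
    "factorial": sp.factorial,
}

_RELATIONS = {
    "lt": sp.Lt,
    "leq": sp.Le,
    "gt": sp.Gt,
    "geq": sp.Ge,
    "eq": sp.Eq,
    "neq": sp.Ne,
}


def _parse_cn(elem):
    ctype = elem.get("type", "real")
    if ctype in ("real", "double"):
        return sp.Float(elem.text.strip())
    if ctype == "integer":
        return sp.Integer(int(elem.text.strip()))
    if ctype in ("e-notation", "rational"):
        parts = [elem.text or ""]
        sep_tail = []
        for child in elem:
            if _tag(child) != "sep":
                raise MathMLError(
                    f"unexpected child <{_tag(child)}> in <cn>", construct=_tag(child)
                )
            sep_tail.append(child.tail or "")
        if len(sep_tail) != 1:
            raise MathMLError("<cn> with separator must have exactly two parts")
        a = parts[0].strip()
        b = sep_tail[0].strip()
        if ctype == "e-notation":
            return sp.Float(f"{a}e{b}")
        return sp.Rational(int(a), int(b))
    raise MathMLError(f"unsupported <cn> type {ctype!r}", construct=f"cn[{ctype}]")


def _parse_csymbol(elem):
    url = elem.get("definitionURL", "")
    if url in _TIME_URLS:
        return TIME_SYMBOL
    if url in _AVOGADRO_URLS:
        return _AVOGADRO
    if url in _DELAY_URLS:
        raise MathMLError("delay terms are not supported", construct="delay")
    raise MathMLError(f"unknown csymbol {url!r}", construct="csymbol")


def parse_mathml(elem) -> sp.Expr:
    """Convert a content-MathML element (or a ``<math>`` wrapper) to sympy.

    ``elem`` may be an :class:`xml.etree.ElementTree.Element` or an XML string.
    """
    if isinstance(elem, str):
        elem = ET.fromstring(elem)
    tag = _tag(elem)
    if tag == "math":
        children = list(elem)
        if len(children) != 1:
            raise MathMLError("<math> must wrap exactly one expression")
        return parse_mathml(children[0])
    if tag == "ci":
        return _symbol(elem.text.strip())
    if tag == "cn":
        return _parse_cn(elem)
    if tag == "csymbol":
        return _parse_csymbol(elem)
    if tag == "true":
        return sp.true
    if tag == "false":
        return sp.false
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    if tag == "notanumber":
        return sp.nan
    if tag == "infinity":
        return sp.oo
    if tag == "apply":
        return _parse_apply(elem)
    if tag == "piecewise":
        return _parse_piecewise(elem)
    if tag == "lambda":
        # SBML function definitions: bound variables then the body
        bvars = []
        body = None
        for child in elem:
            ctag = _tag(child)
            if ctag == "bvar":
                inner = list(child)
                if len(inner) != 1 or _tag(inner[0]) != "ci":
                    raise MathMLError("malformed <bvar>")
                bvars.append(_symbol(inner[0].text.strip()))
            else:
                body = parse_mathml(child)
        if body is None:
            raise MathMLError("<lambda> without a body")
        return sp.Lambda(tuple(bvars), body)
    raise MathMLError(f"unsupported MathML element <{tag}>", construct=tag)


def _parse_apply(elem):
    children = list(elem)
    if not children:
        raise MathMLError("empty <apply>")
    head, *rest = children
    op = _tag(head)
    if op == "root":
        # optional <degree>; default square root
        degree = sp.Integer(2)
        operands = []
        for c in rest:
            if _tag(c) == "degree":
                degree = parse_mathml(list(c)[0])
            else:
                operands.append(parse_mathml(c))
        if len(operands) != 1:
            raise MathMLError("<root> takes one radicand")
        return sp.Pow(operands[0], sp.Integer(1) / degree)
    if op == "log":
        base = sp.Integer(10)
        operands = []
        for c in rest:
            if _tag(c) == "logbase":
                base = parse_mathml(list(c)[0])
            else:
                operands.append(parse_mathml(c))
        if len(operands) != 1:
            raise MathMLError("<log> takes one operand")
        return sp.log(operands[0], base)
    args = [parse_mathml(c) for c in rest]
    if op == "minus":
        if len(args) == 1:
            return -args[0]
        if len(args) == 2:
            return args[0] - args[1]
        raise MathMLError("<minus> takes one or two operands")
    if op == "divide":
        if len(args) != 2:
            raise MathMLError("<divide> takes two operands")
        return args[0] / args[1]
    if op == "power":
        if len(args) != 2:
            raise MathMLError("<power> takes two operands")
        return sp.Pow(args[0], args[1])
    if op in _NARY:
        return _NARY[op](args)
    if op in _UNARY_FUNCS:
        if len(args) != 1:
            raise MathMLError(f"<{op}> takes one operand")
        return _UNARY_FUNCS[op](args[0])
    if op in _RELATIONS:
        if len(args) != 2:
            raise MathMLError(f"<{op}> takes two operands")
        return _RELATIONS[op](args[0], args[1])
    if op == "ci":
        # user-defined function call: resolved later against functionDefinitions
        fname = head.text.strip()
        return sp.Function(fname)(*args)
    if op == "csymbol":
        url = head.get("definitionURL", "")
        if url in _DELAY_URLS:
            raise MathMLError("delay terms are not supported", construct="delay")
        raise MathMLError(f"unknown csymbol head {url!r}", construct="csymbol")
    raise MathMLError(f"unsupported operator <{op}>", construct=op)


def _parse_piecewise(elem):
    pairs = []
    otherwise = None
    for child in elem:
        tag = _tag(child)
        inner = list(child)
        if tag == "piece":
            if len(inner) != 2:
                raise MathMLError("<piece> needs value and condition")
            pairs.append((parse_mathml(inner[0]), parse_mathml(inner[1])))
        elif tag == "otherwise":
            if len(inner) != 1:
                raise MathMLError("<otherwise> needs one value")
            otherwise = parse_mathml(inner[0])
        else:
            raise MathMLError(f"unexpected <{tag}> in <piecewise>", construct=tag)
    if otherwise is not None:
        pairs.append((otherwise, sp.true))
    return sp.Piecewise(*pairs)


# ---------------------------------------------------------------------------
# sympy -> content MathML (used by the SBML export test helper)
# ---------------------------------------------------------------------------


def _el(tag, *children, text=None, **attrib):
    e = ET.Element(f"{{{MATHML_NS}}}{tag}", attrib)
    if text is not None:
        e.text = text
    e.extend(children)
    return e


def _apply(op, *children):
    return _el("apply", _el(op), *children)


def to_mathml(expr: sp.Expr) -> ET.Element:
    """Render a sympy expression as a content-MathML element (no <math> wrapper)."""
    expr = sp.sympify(expr)
    if expr is TIME_SYMBOL or expr == TIME_SYMBOL:
        return _el(
            "csymbol",
            text="time",
            encoding="text",
            definitionURL="http://www.sbml.org/sbml/symbols/time",
        )
    if isinstance(expr, sp.Symbol):
        return _el("ci", text=expr.name)
    if isinstance(expr, sp.Integer):
        return _el("cn", text=str(int(expr)), type="integer")
    if isinstance(expr, sp.Rational):
        return _apply(
            "divide",
            _el("cn", text=str(expr.p), type="integer"),
            _el("cn", text=str(expr.q), type="integer"),
        )
    if isinstance(expr, sp.Float) or expr.is_Number:
        return _el("cn", text=repr(float(expr)))
    if expr is sp.pi:
        return _el("pi")
    if expr is sp.E:
        return _el("exponentiale")
    if expr is sp.true:
        return _el("true")
    if expr is sp.false:
        return _el("false")
    if isinstance(expr, sp.Add):
        return _apply("plus", *[to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Mul):
        return _apply("times", *[to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Pow):
        return _apply("power", to_mathml(expr.base), to_mathml(expr.exp))
    if isinstance(expr, sp.exp):
        return _apply("exp", to_mathml(expr.args[0]))
    if isinstance(expr, sp.log):
        if len(expr.args) == 1:
            return _apply("ln", to_mathml(expr.args[0]))
        return _el(
            "apply",
            _el("log"),
            _el("logbase", to_mathml(expr.args[1])),
            to_mathml(expr.args[0]),
        )
    if isinstance(expr, sp.Abs):
        return _apply("abs", to_mathml(expr.args[0]))
    _trig = {
        sp.sin: "sin",
        sp.cos: "cos",
        sp.tan: "tan",
        sp.asin: "arcsin",
        sp.acos: "arccos",
        sp.atan: "arctan",
        sp.sinh: "sinh",
        sp.cosh: "cosh",
        sp.tanh: "tanh",
        sp.floor: "floor",
        sp.ceiling: "ceiling",
    }
    for cls, name in _trig.items():
        if isinstance(expr, cls):
            return _apply(name, to_mathml(expr.args[0]))
    _rel = {sp.Lt: "lt", sp.Le: "leq", sp.Gt: "gt", sp.Ge: "geq", sp.Eq: "eq", sp.Ne: "neq"}
    for cls, name in _rel.items():
        if isinstance(expr, cls):
            return _apply(name, to_mathml(expr.args[0]), to_mathml(expr.args[1]))
    if isinstance(expr, sp.And):
        return _apply("and", *[to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Or):
        return _apply("or", *[to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Not):
        return _apply("not", to_mathml(expr.args[0]))
    if isinstance(expr, sp.Piecewise):
        pw = _el("piecewise")
        for value, cond in expr.args:
            if cond is sp.true:
                pw.append(_el("otherwise", to_mathml(value)))
            else:
                pw.append(_el("piece", to_mathml(value), to_mathml(cond)))
        return pw
    raise MathMLError(
        f"cannot render {type(expr).__name__} expression to MathML: {expr}",
        construct=type(expr).__name__,
    )


def wrap_math(expr: sp.Expr) -> ET.Element:
    """Wrap an expression in an SBML-style ``<math>`` element."""
    return _el("math", to_mathml(expr))
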