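"""Symbolic partial derivatives and their compiled numeric evaluators.

The central design rule: only *partial* derivatives are ever derived
symbolically (df/dx, df/dp, dx0/dp, dh/dx, dh/dp, dsigma/dp). Total
derivatives such as dy/dp are assembled at runtime by sparse matrix
multiplication and addition — no symbolic dx/dp exists anywhere in the
package.

Sparse carriers use compressed-sparse-column (CSC) layout with entries in
canonical (column, row) order, so repeated evaluations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sps
import sympy as sp

from .exceptions import CompilationError
from .mathml import TIME_SYMBOL
from .model import Model, validate_model


def _is_zero(expr: sp.Expr) -> bool:
    """Bounded-effort zero recognition: expand, then simplify small residuals.

    Entries that cannot be proven zero stay in the sparsity pattern
    (correctness over minimality)."""
    e = sp.expand(expr)
    if e == 0:
        return True
    if e.is_Number:
        return e == 0
    if len(e.free_symbols) <= 6 and e.count_ops() <= 64:
        return sp.simplify(e) == 0
    return False


def sparsity_pattern(matrix) -> list:
    """Structural nonzeros of a symbolic matrix as a row-major list of (row, col)."""
    pattern = []
    for i in range(matrix.rows):
        for j in range(matrix.cols):
            if not _is_zero(matrix[i, j]):
                pattern.append((i, j))
    return pattern


@dataclass
class PartialDerivativeSet:
    """All first-order symbolic partials of a model, with sparsity patterns.

    Matrices are sympy Matrices; patterns are row-major (row, col) lists of
    the structurally nonzero entries.
    """

    dfdx: sp.Matrix
    dfdp: sp.Matrix
    dx0dp: sp.Matrix
    dhdx: sp.Matrix
    dhdp: sp.Matrix
    dsigmadp: sp.Matrix
    patterns: dict

    def pattern(self, name):
        return self.patterns[name]


def derive_partials(model: Model) -> PartialDerivativeSet:
    """Differentiate f, x0, h and sigma symbolically with respect to x and p."""
    diags = validate_model(model)
    if diags:
        raise CompilationError(
            "model failed validation: " + "; ".join(diags)
        )
    x = model.state_symbols
    p = model.parameter_symbols
    f = sp.Matrix(model.rhs) if model.rhs else sp.zeros(0, 1)
    x0 = sp.Matrix(model.initials) if model.initials else sp.zeros(0, 1)
    h = sp.Matrix([model.observables[o] for o in model.observable_ids]) \
        if model.observables else sp.zeros(0, 1)
    sigma = sp.Matrix(
        [model.noise_formulas.get(o, sp.Integer(1)) for o in model.observable_ids]
    ) if model.observables else sp.zeros(0, 1)

    def jac(vec, wrt, what):
        if vec.rows == 0 or not wrt:
            return sp.zeros(vec.rows, len(wrt))
        try:
            out = vec.jacobian(sp.Matrix(wrt))
        except Exception as exc:  # non-differentiable expression
            raise CompilationError(
                f"cannot differentiate {what}: {exc}"
            ) from exc
        for entry in out:
            if entry.has(sp.Derivative):
                raise CompilationError(
                    f"derivative of {what} left unevaluated: {entry}"
                )
        return out

    mats = {
        "dfdx": jac(f, x, "f w.r.t. x"),
        "dfdp": jac(f, p, "f w.r.t. p"),
        "dx0dp": jac(x0, p, "x0 w.r.t. p"),
        "dhdx": jac(h, x, "h w.r.t. x"),
        "dhdp": jac(h, p, "h w.r.t. p"),
        "dsigmadp": jac(sigma, p, "sigma w.r.t. p"),
    }
    patterns = {name: sparsity_pattern(m) for name, m in mats.items()}
    return PartialDerivativeSet(patterns=patterns, **mats)


# ---------------------------------------------------------------------------
# numeric compilation
# ---------------------------------------------------------------------------


def _lambdify(args, exprs, what):
    try:
        fn = sp.lambdify(args, exprs, modules=["numpy", {"Heaviside": np.heaviside}])
    except Exception as exc:
        raise CompilationError(f"compilation of {what} failed: {exprs}: {exc}") from exc
    return fn


class _VectorEval:
    """Callable returning a flat float array; pure (no state)."""

    def __init__(self, syms, exprs, what):
        self._n = len(exprs)
        self._fn = _lambdify(syms, list(exprs), what)

    def __call__(self, *flat):
        out = self._fn(*flat)
        return np.asarray(out, dtype=float).reshape(self._n)


class _SparseEval:
    """Evaluate a symbolic matrix into a CSC matrix honoring a fixed pattern.

    Entries are stored in canonical (column, row) order; the returned matrix
    shares no state between calls.
    """

    def __init__(self, syms, matrix, pattern, what):
        self.shape = (matrix.rows, matrix.cols)
        order = sorted(pattern, key=lambda rc: (rc[1], rc[0]))
        self.pattern = list(pattern)  # row-major, as declared
        self._rows = np.array([r for r, _ in order], dtype=np.int32)
        self._cols = np.array([c for _, c in order], dtype=np.int32)
        exprs = [matrix[r, c] for r, c in order]
        self._fn = _lambdify(syms, exprs, what) if exprs else None
        indptr = np.zeros(self.shape[1] + 1, dtype=np.int32)
        for c in self._cols:
            indptr[c + 1] += 1
        self._indptr = np.cumsum(indptr).astype(np.int32)
        self._indices = self._rows.copy()

    def __call__(self, *flat):
        if self._fn is None:
            data = np.zeros(0)
        else:
            data = np.asarray(self._fn(*flat), dtype=float).reshape(len(self._rows))
        return sps.csc_matrix(
            (data, self._indices.copy(), self._indptr.copy()), shape=self.shape
        )


@dataclass
class CompiledModel:
    """Numeric evaluators for a model and its partial derivatives.

    Call signatures follow each quantity's true dependencies:

    ==============  =======================
    f, dfdx, dfdp   ``(x, p, k, t)``
    h, dhdx, dhdp   ``(x, p, k)``
    x0, dx0dp       ``(p, k)``
    sigma, dsigmadp ``(p, k)``
    ==============  =======================

    Dense quantities return ``numpy`` arrays; partial-derivative matrices
    return CSC matrices whose pattern equals the declared symbolic pattern.
    """

    model: Model
    partials: PartialDerivativeSet
    n_states: int
    n_observables: int
    n_parameters: int
    n_fixed_parameters: int
    _ev: dict

    @property
    def dims(self):
        return (
            self.n_states,
            self.n_observables,
            self.n_parameters,
            self.n_fixed_parameters,
        )

    def f(self, x, p, k, t=0.0):
        return self._ev["f"](*x, *p, *k, t)

    def x0(self, p, k):
        return self._ev["x0"](*p, *k)

    def h(self, x, p, k):
        return self._ev["h"](*x, *p, *k)

    def sigma(self, p, k):
        return self._ev["sigma"](*p, *k)

    def dfdx(self, x, p, k, t=0.0):
        return self._ev["dfdx"](*x, *p, *k, t)

    def dfdx_dense(self, x, p, k, t=0.0):
        return self.dfdx(x, p, k, t).toarray()

    def dfdp(self, x, p, k, t=0.0):
        return self._ev["dfdp"](*x, *p, *k, t)

    def dx0dp(self, p, k):
        return self._ev["dx0dp"](*p, *k)

    def dhdx(self, x, p, k):
        return self._ev["dhdx"](*x, *p, *k)

    def dhdp(self, x, p, k):
        return self._ev["dhdp"](*x, *p, *k)

    def dsigmadp(self, p, k):
        return self._ev["dsigmadp"](*p, *k)


def compile_functions(model: Model, partials: PartialDerivativeSet | None = None) -> CompiledModel:
    """Compile a model and its partials into pure numeric evaluators."""
    if partials is None:
        partials = derive_partials(model)
    x = model.state_symbols
    p = model.parameter_symbols
    k = model.fixed_parameter_symbols
    xpkt = [*x, *p, *k, TIME_SYMBOL]
    xpk = [*x, *p, *k]
    pk = [*p, *k]

    obs_exprs = [model.observables[o] for o in model.observable_ids]
    sigma_exprs = [
        model.noise_formulas.get(o, sp.Integer(1)) for o in model.observable_ids
    ]

    ev = {
        "f": _VectorEval(xpkt, model.rhs, "f"),
        "x0": _VectorEval(pk, model.initials, "x0"),
        "h": _VectorEval(xpk, obs_exprs, "h"),
        "sigma": _VectorEval(pk, sigma_exprs, "sigma"),
        "dfdx": _SparseEval(xpkt, partials.dfdx, partials.pattern("dfdx"), "dfdx"),
        "dfdp": _SparseEval(xpkt, partials.dfdp, partials.pattern("dfdp"), "dfdp"),
        "dx0dp": _SparseEval(pk, partials.dx0dp, partials.pattern("dx0dp"), "dx0dp"),
        "dhdx": _SparseEval(xpk, partials.dhdx, partials.pattern("dhdx"), "dhdx"),
        "dhdp": _SparseEval(xpk, partials.dhdp, partials.pattern("dhdp"), "dhdp"),
        "dsigmadp": _SparseEval(
            pk, partials.dsigmadp, partials.pattern("dsigmadp"), "dsigmadp"
        ),
    }
    return CompiledModel(
        model=model,
        partials=partials,
        n_states=model.n_states,
        n_observables=model.n_observables,
        n_parameters=model.n_parameters,
        n_fixed_parameters=model.n_fixed_parameters,
        _ev=ev,
    )


def compile_model(model: Model) -> CompiledModel:
    """Convenience wrapper: derive partials, then compile."""
    return compile_functions(model, derive_partials(model))


def assemble_output_sensitivity(dhdx, sx, dhdp) -> np.ndarray:
    """Total output sensitivity dy/dp = dhdx @ sx + dhdp at one time point.

    ``dhdx`` and ``dhdp`` may be sparse (CSC) or dense; ``sx`` is the dense
    n_x-by-n_p state sensitivity. Returns a dense n_y-by-n_p array.
    """
    sx = np.asarray(sx, dtype=float)
    n_y = dhdx.shape[0]
    n_x = dhdx.shape[1]
    if sx.shape[0] != n_x or dhdp.shape[0] != n_y or dhdp.shape[1] != sx.shape[1]:
        raise ValueError(
            f"shape mismatch: dhdx {dhdx.shape}, sx {sx.shape}, dhdp {dhdp.shape}"
        )
    prod = dhdx @ sx
    if sps.issparse(prod):
        prod = prod.toarray()
    direct = dhdp.toarray() if sps.issparse(dhdp) else np.asarray(dhdp, dtype=float)
    return np.asarray(prod, dtype=float) + direct


def dump_patterns(partials: PartialDerivativeSet) -> str:
    """Plain-text report of all partial expressions and sparsity patterns."""
    lines = []
    for name in ("dfdx", "dfdp", "dx0dp", "dhdx", "dhdp", "dsigmadp"):
        mat = getattr(partials, name)
        pat = partials.pattern(name)
        lines.append(f"{name} ({mat.rows}x{mat.cols}), {len(pat)} structural nonzeros")
        for r, c in pat:
            lines.append(f"  [{r},{c}] = {mat[r, c]}")
    return "\n".join(lines) + "\n"
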