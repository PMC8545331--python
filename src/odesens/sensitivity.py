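"""Forward, adjoint and steady-state sensitivity analysis.

Forward sensitivities augment the ODE with one linear system per parameter,

    ds_j/dt = J s_j + df/dp_j,    s_j(t0) = dx0/dp_j,

integrated jointly with the state; the Jacobian J is evaluated once per
right-hand-side call and reused across all parameters. Output sensitivities
dy/dp are assembled at output times by the runtime sparse product
``dhdx @ sx + dhdp`` (never derived symbolically).

The adjoint method computes the gradient of a discrete-data negative
log-likelihood with a single backward integration: between datapoints the
adjoint state obeys dλ/dt = −Jᵀ λ; at each datapoint λ jumps by
(∂g_i/∂x)ᵀ = dhdxᵀ ∂g_i/∂y; the quadrature q = ∫ λᵀ (∂f/∂p) dt accumulates
alongside, and the gradient is

    ∇G = q + Σ_i ∂g_i/∂p|direct + λ(t0)ᵀ dx0/dp .

Steady-state sensitivities come from the implicit-function theorem,
J s* = −∂f/∂p, solved with one factorisation; a singular Jacobian
(conservation laws) triggers a simulate-to-convergence fallback that is
flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sps
import scipy.sparse.linalg as spla

from .codegen import CompiledModel, assemble_output_sensitivity
from .exceptions import (
    IntegrationFailureError,
    SingularJacobianError,
    SteadyStateFailureError,
)
from .solver import (
    LinearSolver,
    SolverConfig,
    SolverStats,
    SteadyState,
    Trajectory,
    _integrate,
    wrms,
)

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class DataPoint:
    """One measurement: observable ``observable_index`` at time ``t``.

    ``sigma_override`` replaces the model noise formula with a constant for
    this point (no dσ/dp contribution then); ``distribution`` is ``normal``
    or ``lognormal``.
    """

    t: float
    observable_index: int
    value: float
    sigma_override: float | None = None
    distribution: str = "normal"


@dataclass
class ForwardSensitivityResult:
    trajectory: Trajectory
    sx: np.ndarray  # (M+1) x n_x x n_p
    sy: np.ndarray  # (M+1) x n_y x n_p


@dataclass
class GradientResult:
    value: float
    gradient: np.ndarray
    method: str  # forward | adjoint | steady_state | finite_difference
    per_condition: dict = field(default_factory=dict)


@dataclass
class SteadyStateSensitivities:
    sx: np.ndarray  # n_x x n_p
    method: str     # linear_solve | simulation
    fallback_used: bool = False


# ---------------------------------------------------------------------------
# forward sensitivities
# ---------------------------------------------------------------------------


def _augmented_system(cm: CompiledModel, p, k, cfg: SolverConfig):
    n, n_p = cm.n_states, cm.n_parameters

    def rhs(t, z):
        x = z[:n]
        sx = z[n:].reshape(n, n_p, order="F")
        f = cm.f(x, p, k, t)
        J = cm.dfdx(x, p, k, t)          # one Jacobian evaluation per call,
        ds = J @ sx + cm.dfdp(x, p, k, t)  # shared by all parameter columns
        ds = np.asarray(ds.todense()) if sps.issparse(ds) else np.asarray(ds)
        return np.concatenate([f, ds.ravel(order="F")])

    sparse_mode = cfg.linear_solver == LinearSolver.sparse

    def jac(t, z):
        # block-diagonal approximation diag(J, J, ..., J): exact for the state
        # block, ignores the s->x coupling; Newton still converges on the
        # correct nonlinear system, only its rate is affected.
        x = z[:n]
        J = cm.dfdx(x, p, k, t)
        blocks = [J] * (1 + n_p)
        if sparse_mode:
            return sps.block_diag(blocks, format="csc")
        return sla.block_diag(*[np.asarray(b.todense()) for b in blocks])

    return rhs, jac


def forward_sensitivities(
    cm: CompiledModel,
    p,
    k,
    x_init,
    timepoints,
    cfg: SolverConfig | None = None,
    sx_init=None,
) -> ForwardSensitivityResult:
    """Integrate states and state sensitivities jointly; assemble dy/dp."""
    if cfg is None:
        cfg = SolverConfig()
    p = np.asarray(p, dtype=float)
    k = np.asarray(k, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    x_init = np.asarray(x_init, dtype=float)
    n, n_p, n_y = cm.n_states, cm.n_parameters, cm.n_observables
    if sx_init is None:
        sx_init = cm.dx0dp(p, k).toarray()
    sx_init = np.asarray(sx_init, dtype=float).reshape(n, n_p)

    stats = SolverStats()
    z0 = np.concatenate([x_init, sx_init.ravel(order="F")])
    rhs, jac = _augmented_system(cm, p, k, cfg)
    t0, t1 = float(timepoints[0]), float(timepoints[-1])
    if t1 > t0:
        _, zs, interp, _ = _integrate(rhs, jac, z0, t0, t1, cfg, timepoints, stats)
    else:
        zs, interp = np.tile(z0, (len(timepoints), 1)), None

    xs = zs[:, :n]
    sx = zs[:, n:].reshape(len(timepoints), n, n_p, order="F")
    ys = np.array([cm.h(x, p, k) for x in xs]).reshape(len(timepoints), n_y)
    sy = np.array(
        [
            assemble_output_sensitivity(
                cm.dhdx(x, p, k), s, cm.dhdp(x, p, k)
            )
            for x, s in zip(xs, sx)
        ]
    ).reshape(len(timepoints), n_y, n_p)
    traj = Trajectory(
        timepoints=timepoints,
        states=xs,
        outputs=ys,
        stats=stats,
        interpolant=(lambda t: np.atleast_1d(interp(t))[:n]) if interp else None,
    )
    return ForwardSensitivityResult(trajectory=traj, sx=sx, sy=sy)


# ---------------------------------------------------------------------------
# likelihood point terms (shared by forward/adjoint objective gradients)
# ---------------------------------------------------------------------------


def nll_point(y, sigma, ybar, distribution="normal"):
    """Value and partials of one datapoint's negative log-likelihood.

    Returns ``(g, dg/dy, dg/dsigma)``. Normal noise:
    g = 0.5 ((ybar−y)/σ)² + 0.5 log(2π σ²); log-normal applies the same on
    log-transformed values plus the Jacobian term log(ybar).
    """
    if sigma <= 0:
        raise ValueError(f"noise scale must be positive, got {sigma}")
    if distribution == "normal":
        r = ybar - y
        g = 0.5 * (r / sigma) ** 2 + 0.5 * (LOG2PI + 2.0 * math.log(sigma))
        dgdy = -r / sigma**2
        dgdsigma = -(r**2) / sigma**3 + 1.0 / sigma
        return g, dgdy, dgdsigma
    if distribution == "lognormal":
        if y <= 0 or ybar <= 0:
            raise ValueError("log-normal noise requires positive values")
        r = math.log(ybar) - math.log(y)
        g = 0.5 * (r / sigma) ** 2 + 0.5 * (LOG2PI + 2.0 * math.log(sigma)) + math.log(ybar)
        dgdy = -r / (sigma**2 * y)
        dgdsigma = -(r**2) / sigma**3 + 1.0 / sigma
        return g, dgdy, dgdsigma
    raise ValueError(f"unsupported noise distribution {distribution!r}")


def _point_values(cm, p, k, datapoints, y_at):
    """Evaluate g, dg/dy, dg/dsigma and σ for each datapoint."""
    sigmas_model = cm.sigma(p, k)
    out = []
    for dp in datapoints:
        y = y_at(dp)
        sigma = dp.sigma_override if dp.sigma_override is not None else float(
            sigmas_model[dp.observable_index]
        )
        g, dgdy, dgds = nll_point(y, sigma, dp.value, dp.distribution)
        out.append((g, dgdy, dgds, sigma))
    return out


def _direct_gradient_terms(cm, p, k, x_at, datapoints, terms):
    """Σ_i ∂g_i/∂p through dhdp and (for model-σ points) dσdp."""
    n_p = cm.n_parameters
    grad = np.zeros(n_p)
    dsigmadp = cm.dsigmadp(p, k).toarray()
    for dp, (g, dgdy, dgds, sigma) in zip(datapoints, terms):
        x = x_at(dp)
        dhdp = cm.dhdp(x, p, k).toarray()
        grad += dgdy * dhdp[dp.observable_index, :]
        if dp.sigma_override is None:
            grad += dgds * dsigmadp[dp.observable_index, :]
    return grad


def forward_gradient(
    cm, p, k, x_init, datapoints, cfg=None, sx_init=None, t0=0.0
) -> GradientResult:
    """Objective value and gradient via forward sensitivities."""
    if cfg is None:
        cfg = SolverConfig()
    datapoints = list(datapoints)
    times = sorted({t0} | {dp.t for dp in datapoints})
    fsr = forward_sensitivities(cm, p, k, x_init, times, cfg, sx_init=sx_init)
    t_index = {t: i for i, t in enumerate(times)}

    def y_at(dp):
        return float(fsr.trajectory.outputs[t_index[dp.t], dp.observable_index])

    terms = _point_values(cm, p, k, datapoints, y_at)
    value = sum(t[0] for t in terms)
    grad = np.zeros(cm.n_parameters)
    dsigmadp = cm.dsigmadp(p, k).toarray()
    for dp, (g, dgdy, dgds, sigma) in zip(datapoints, terms):
        grad += dgdy * fsr.sy[t_index[dp.t], dp.observable_index, :]
        if dp.sigma_override is None:
            grad += dgds * dsigmadp[dp.observable_index, :]
    return GradientResult(value=float(value), gradient=grad, method="forward")


# ---------------------------------------------------------------------------
# adjoint gradient
# ---------------------------------------------------------------------------


def adjoint_gradient(
    cm: CompiledModel,
    p,
    k,
    x_init,
    datapoints,
    cfg: SolverConfig | None = None,
    sx0=None,
    t0=0.0,
) -> GradientResult:
    """Objective value and gradient via one backward adjoint integration.

    ``sx0`` is the sensitivity of the initial state (n_x × n_p); it defaults
    to dx0/dp and is the hook by which pre-equilibration sensitivities enter.
    """
    if cfg is None:
        cfg = SolverConfig()
    p = np.asarray(p, dtype=float)
    k = np.asarray(k, dtype=float)
    x_init = np.asarray(x_init, dtype=float)
    datapoints = list(datapoints)
    if not datapoints:
        return GradientResult(0.0, np.zeros(cm.n_parameters), "adjoint")
    n, n_p = cm.n_states, cm.n_parameters
    t0 = float(t0)
    t_data = sorted({dp.t for dp in datapoints})
    if t_data[0] < t0:
        raise ValueError(f"datapoint at t={t_data[0]} precedes t0={t0}")
    T = t_data[-1]

    # forward pass with dense interpolant for the backward replay
    from .solver import simulate

    traj = simulate(cm, p, k, x_init, sorted({t0, *t_data}), cfg)

    def x_of(t):
        return traj.state_at(t)

    def y_at(dp):
        x = x_of(dp.t)
        return float(cm.h(x, p, k)[dp.observable_index])

    terms = _point_values(cm, p, k, datapoints, y_at)
    value = sum(t_[0] for t_ in terms)

    # backward sweep: λ jumps at datapoint times, quadrature alongside
    lam = np.zeros(n)
    quad = np.zeros(n_p)
    stats = SolverStats()
    by_time = {}
    for dp, term in zip(datapoints, terms):
        by_time.setdefault(dp.t, []).append((dp, term))

    sparse_mode = cfg.linear_solver == LinearSolver.sparse

    def rhs_b(t, z):
        x = x_of(t)
        lam_ = z[:n]
        J = cm.dfdx(x, p, k, t)
        fp = cm.dfdp(x, p, k, t)
        dlam = -(J.T @ lam_)
        dq = -(fp.T @ lam_)
        return np.concatenate([np.asarray(dlam).ravel(), np.asarray(dq).ravel()])

    def jac_b(t, z):
        x = x_of(t)
        J = cm.dfdx(x, p, k, t)
        fp = cm.dfdp(x, p, k, t)
        if sparse_mode:
            return sps.bmat(
                [
                    [-J.T, None],
                    [-fp.T, sps.csc_matrix((n_p, n_p))],
                ],
                format="csc",
            )
        out = np.zeros((n + n_p, n + n_p))
        out[:n, :n] = -np.asarray(J.todense()).T
        out[n:, :n] = -np.asarray(fp.todense()).T
        return out

    def apply_jumps(t):
        nonlocal lam
        x = x_of(t)
        dhdx = cm.dhdx(x, p, k)
        for dp, (g, dgdy, dgds, sigma) in by_time.get(t, []):
            dgdx = dhdx.T @ _unit(cm.n_observables, dp.observable_index) * dgdy
            lam = lam + np.asarray(dgdx).ravel()

    times_desc = sorted(by_time, reverse=True)
    t_hi = times_desc[0]
    apply_jumps(t_hi)
    remaining = [t for t in times_desc[1:]] + ([t0] if times_desc[-1] > t0 else [])
    for t_lo in remaining:
        z0 = np.concatenate([lam, quad])
        try:
            _, _, interp, t_stop = _integrate(
                rhs_b, jac_b, z0, t_hi, t_lo, cfg, [], stats
            )
        except IntegrationFailureError as exc:
            raise IntegrationFailureError(
                f"adjoint backward pass failed: {exc}", t_failure=exc.t_failure
            ) from exc
        z_end = np.atleast_1d(interp(t_lo)).astype(float) if interp else z0
        lam, quad = z_end[:n], z_end[n:]
        if t_lo in by_time:
            apply_jumps(t_lo)
        t_hi = t_lo

    grad = quad.copy()
    grad += _direct_gradient_terms(cm, p, k, lambda dp: x_of(dp.t), datapoints, terms)
    if sx0 is None:
        sx0 = cm.dx0dp(p, k).toarray()
    grad += np.asarray(sx0, dtype=float).reshape(n, n_p).T @ lam
    return GradientResult(value=float(value), gradient=grad, method="adjoint")


def _unit(n, i):
    e = np.zeros(n)
    e[i] = 1.0
    return e


# ---------------------------------------------------------------------------
# steady-state sensitivities
# ---------------------------------------------------------------------------


def steadystate_sensitivities(
    cm: CompiledModel,
    ss: SteadyState,
    p,
    k,
    cfg: SolverConfig | None = None,
    x_init=None,
    sx_init=None,
) -> SteadyStateSensitivities:
    """s* = −J⁻¹ ∂f/∂p at a steady state (implicit-function theorem).

    One factorisation of J, n_p right-hand sides. If J is singular
    (conservation laws), falls back to integrating the augmented forward
    system from ``x_init`` (default: the steady state itself) until the
    sensitivities converge; the result records which path was taken.
    """
    if cfg is None:
        cfg = SolverConfig()
    p = np.asarray(p, dtype=float)
    k = np.asarray(k, dtype=float)
    x_ss = np.asarray(ss.x_ss, dtype=float)
    n, n_p = cm.n_states, cm.n_parameters
    if ss.residual_norm >= 1.0:
        raise ValueError("steady state has not converged (residual_norm >= 1)")
    fp = cm.dfdp(x_ss, p, k, 0.0)
    try:
        if cfg.linear_solver == LinearSolver.sparse:
            J = cm.dfdx(x_ss, p, k, 0.0).tocsc()
            lu = spla.splu(J)
            # splu does not signal exact singularity reliably; check residual
            sx = -lu.solve(np.asarray(fp.todense()))
            if not np.all(np.isfinite(sx)) or np.linalg.norm(
                J @ sx + np.asarray(fp.todense())
            ) > 1e-6 * max(1.0, float(np.linalg.norm(fp.todense()))):
                raise SingularJacobianError("sparse LU produced an inconsistent solve")
        else:
            J = cm.dfdx_dense(x_ss, p, k, 0.0)
            cond = np.linalg.cond(J) if n else 0.0
            if not np.isfinite(cond) or cond > 1e14:
                raise SingularJacobianError(
                    "Jacobian is singular at the steady state"
                )
            sx = -sla.solve(J, np.asarray(fp.todense()))
        return SteadyStateSensitivities(
            sx=np.asarray(sx).reshape(n, n_p), method="linear_solve"
        )
    except (SingularJacobianError, RuntimeError):
        pass

    # fallback: simulate the augmented system to convergence
    x_start = np.asarray(x_init, dtype=float) if x_init is not None else x_ss
    if sx_init is None:
        sx_init = cm.dx0dp(p, k).toarray()
    sx_start = np.asarray(sx_init, dtype=float).reshape(n, n_p)
    rhs, jac = _augmented_system(cm, p, k, cfg)
    z0 = np.concatenate([x_start, sx_start.ravel(order="F")])
    stats = SolverStats()

    def converged(t, z):
        dz = rhs(t, z)
        return wrms(dz, z, cfg) < 1.0

    try:
        _, _, interp, t_stop = _integrate(
            rhs, jac, z0, 0.0, cfg.ss_t_max, cfg, [], stats, converged=converged
        )
    except IntegrationFailureError as exc:
        raise SteadyStateFailureError(
            f"augmented steady-state simulation failed: {exc}"
        ) from exc
    z_end = np.atleast_1d(interp(t_stop)).astype(float) if interp else z0
    if wrms(rhs(t_stop, z_end), z_end, cfg) >= 1.0:
        raise SteadyStateFailureError(
            "augmented system did not reach steady state before t exceeded "
            f"{cfg.ss_t_max:g}"
        )
    sx = z_end[n:].reshape(n, n_p, order="F")
    return SteadyStateSensitivities(sx=sx, method="simulation", fallback_used=True)


# ---------------------------------------------------------------------------
# finite differences (test oracle and check-gradient backend)
# ---------------------------------------------------------------------------


def finite_difference_gradient(objective, p, scheme="central", step=None):
    """Finite-difference gradient of a scalar objective on the given scale.

    Default step is 1e−5 · max(|p_j|, 1) per coordinate. Used as the
    independent oracle in gradient checks, never as the production gradient.
    """
    p = np.asarray(p, dtype=float)
    if scheme not in ("central", "forward"):
        raise ValueError(f"unknown scheme {scheme!r}")
    grad = np.zeros_like(p)
    f0 = objective(p) if scheme == "forward" else None
    for j in range(len(p)):
        hj = step if step is not None else 1e-5 * max(abs(p[j]), 1.0)
        e = np.zeros_like(p)
        e[j] = hj
        if scheme == "central":
            grad[j] = (objective(p + e) - objective(p - e)) / (2.0 * hj)
        else:
            grad[j] = (objective(p + e) - f0) / hj
    return grad
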