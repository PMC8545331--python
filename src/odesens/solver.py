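"""Stiff ODE integration and steady-state solving.

The default integrator is a variable-order, variable-step implicit multistep
(BDF) method using the model's analytic Jacobian in its Newton iterations;
the nonstiff option is a multistep Adams method with automatic stiffness
switching (LSODA). The linear algebra inside the implicit steps is selected
by ``SolverConfig.linear_solver``: ``dense`` factorises a dense Jacobian,
``sparse`` hands the integrator a CSC Jacobian so a sparse LU is used.

Steady states are found Newton-first (damped, analytic Jacobian), with a
simulation fallback driven by the weighted-RMS convergence criterion

    sqrt( (1/n_x) * sum_i ( f_i / (atol*c + rtol*c*|x_i|) )^2 ) < 1,

with ``c = ss_tol_factor`` — the weighted-norm convention of the multistep
solver family used for step control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import scipy.integrate as sci
import scipy.linalg as sla

from .codegen import CompiledModel
from .exceptions import (
    IntegrationFailureError,
    NotSupportedError,
    SingularJacobianError,
    SteadyStateFailureError,
)


class LinearSolver(str, Enum):
    dense = "dense"
    sparse = "sparse"
    iterative = "iterative"


class Method(str, Enum):
    stiff_multistep = "stiff_multistep"
    nonstiff_multistep = "nonstiff_multistep"


@dataclass
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-12
    max_steps: int = 100_000
    linear_solver: LinearSolver = LinearSolver.dense
    method: Method = Method.stiff_multistep
    ss_tol_factor: float = 10.0
    newton_max_iters: int = 20
    ss_t_max: float = 1e10

    def __post_init__(self):
        self.linear_solver = LinearSolver(self.linear_solver)
        self.method = Method(self.method)
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    def tighter(self, factor=10.0) -> "SolverConfig":
        return replace(self, rtol=self.rtol / factor, atol=self.atol / factor)


@dataclass
class SolverStats:
    steps: int = 0
    rhs_evaluations: int = 0
    jacobian_evaluations: int = 0


@dataclass
class Trajectory:
    """Simulated states and outputs at requested timepoints.

    ``interpolant`` is valid over the full integration span and is what the
    adjoint backward pass replays the forward solution from.
    """

    timepoints: np.ndarray
    states: np.ndarray   # (M+1) x n_x
    outputs: np.ndarray  # (M+1) x n_y
    stats: SolverStats
    interpolant: object | None = None

    def state_at(self, t):
        t = float(t)
        if self.interpolant is None or t <= self.timepoints[0]:
            if np.isclose(t, self.timepoints[0]):
                return self.states[0].copy()
        if self.interpolant is None:
            idx = int(np.argmin(np.abs(self.timepoints - t)))
            if not np.isclose(self.timepoints[idx], t):
                raise ValueError(f"no dense output available at t={t}")
            return self.states[idx].copy()
        return np.atleast_1d(self.interpolant(t)).astype(float)


@dataclass
class SteadyState:
    x_ss: np.ndarray
    residual_norm: float
    method_used: str           # newton | simulation | newton_after_simulation
    t_reached: float | None = None
    stats: SolverStats = field(default_factory=SolverStats)


def _select_integrator(cfg: SolverConfig):
    if cfg.method == Method.stiff_multistep:
        return sci.BDF
    return sci.LSODA


def _make_jac(cm: CompiledModel, p, k, cfg: SolverConfig):
    if cfg.linear_solver == LinearSolver.iterative:
        raise NotSupportedError(
            "iterative linear solver is not implemented; use 'dense' or 'sparse'"
        )
    if cfg.linear_solver == LinearSolver.sparse:
        return lambda t, x: cm.dfdx(x, p, k, t)
    return lambda t, x: cm.dfdx_dense(x, p, k, t)


def _integrate(rhs, jac, x0, t0, t1, cfg: SolverConfig, timepoints, stats,
               converged=None):
    """Drive a scipy step integrator from t0 to t1 under a step budget.

    Returns ``(ts, xs, interpolant, t_stop)`` where ``ts``/``xs`` hold values
    at the requested ``timepoints`` (all must lie in [t0, t1]) and ``t_stop``
    is where integration actually ended (early if ``converged`` fires).
    """
    cls = _select_integrator(cfg)
    kwargs = dict(rtol=cfg.rtol, atol=cfg.atol, jac=jac)
    if cls is sci.LSODA:
        # LSODA takes the jacobian as a callable returning dense
        def _dense_jac(t, x):
            J = jac(t, x)
            return np.asarray(J.toarray() if hasattr(J, "toarray") else J, dtype=float)

        kwargs = dict(rtol=cfg.rtol, atol=cfg.atol, jac=_dense_jac)
    solver = cls(rhs, t0, np.asarray(x0, dtype=float), t_bound=t1, **kwargs)
    ts = [t0]
    segments = []
    while solver.status == "running":
        if stats.steps >= cfg.max_steps:
            raise IntegrationFailureError(
                f"maximum number of steps ({cfg.max_steps}) exceeded",
                t_failure=solver.t,
            )
        solver.step()
        if solver.status == "failed":
            raise IntegrationFailureError(
                "integrator step failed (step-size underflow)", t_failure=solver.t
            )
        stats.steps += 1
        segments.append(solver.dense_output())
        ts.append(solver.t)
        if converged is not None and converged(solver.t, solver.y):
            break
    stats.rhs_evaluations += int(getattr(solver, "nfev", 0))
    stats.jacobian_evaluations += int(getattr(solver, "njev", 0))
    interp = sci.OdeSolution(ts, segments) if segments else None
    t_stop = ts[-1]
    out_t, out_x = [], []
    for t in timepoints:
        if t <= t0:
            out_t.append(t)
            out_x.append(np.asarray(x0, dtype=float))
        elif interp is not None and t <= t_stop + 1e-12 * max(1.0, abs(t_stop)):
            out_t.append(t)
            out_x.append(np.atleast_1d(interp(min(t, t_stop))).astype(float))
    return np.array(out_t), np.array(out_x), interp, t_stop


def simulate(cm: CompiledModel, p, k, x_init, timepoints, cfg: SolverConfig | None = None) -> Trajectory:
    """Integrate dx/dt = f(x,p,k,t) and evaluate observables at ``timepoints``."""
    if cfg is None:
        cfg = SolverConfig()
    p = np.asarray(p, dtype=float)
    k = np.asarray(k, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.ndim != 1 or len(timepoints) == 0:
        raise ValueError("timepoints must be a non-empty 1-D array")
    if np.any(np.diff(timepoints) < 0):
        raise ValueError("timepoints must be sorted ascending")
    x_init = np.asarray(x_init, dtype=float)
    if x_init.shape != (cm.n_states,):
        raise ValueError(f"x_init must have length {cm.n_states}")

    stats = SolverStats()
    rhs = lambda t, x: cm.f(x, p, k, t)
    jac = _make_jac(cm, p, k, cfg)

    t0, t1 = float(timepoints[0]), float(timepoints[-1])
    if t1 > t0:
        _, xs, interp, _ = _integrate(rhs, jac, x_init, t0, t1, cfg, timepoints, stats)
    else:
        xs = np.tile(x_init, (len(timepoints), 1))
        interp = None
    ys = np.array([cm.h(x, p, k) for x in xs]).reshape(len(timepoints), cm.n_observables)
    return Trajectory(
        timepoints=timepoints, states=xs, outputs=ys, stats=stats, interpolant=interp
    )


def jacobian_at(cm: CompiledModel, x, p, k, t=0.0, cfg: SolverConfig | None = None):
    """df/dx at a point, dense or CSC per the configured linear solver."""
    if cfg is None or cfg.linear_solver == LinearSolver.dense:
        return cm.dfdx_dense(x, p, k, t)
    if cfg.linear_solver == LinearSolver.sparse:
        return cm.dfdx(x, p, k, t)
    raise NotSupportedError("iterative linear solver is not implemented")


def wrms(f_val, x, cfg: SolverConfig) -> float:
    """Weighted RMS norm of the rhs used as the steady-state criterion."""
    f_val = np.asarray(f_val, dtype=float)
    x = np.asarray(x, dtype=float)
    if f_val.size == 0:
        return 0.0
    w = cfg.atol * cfg.ss_tol_factor + cfg.rtol * cfg.ss_tol_factor * np.abs(x)
    return float(np.sqrt(np.mean((f_val / w) ** 2)))


def _newton(cm, p, k, x, cfg, stats):
    """Damped Newton on f(x)=0; raises SingularJacobianError on rank loss."""
    x = np.asarray(x, dtype=float).copy()
    fx = cm.f(x, p, k, 0.0)
    res = wrms(fx, x, cfg)
    for _ in range(cfg.newton_max_iters):
        if res < 1.0:
            return x, res
        J = cm.dfdx_dense(x, p, k, 0.0)
        stats.jacobian_evaluations += 1
        n = J.shape[0]
        if n == 0:
            return x, 0.0
        cond_bound = np.linalg.cond(J) if n else 0.0
        if not np.isfinite(cond_bound) or cond_bound > 1e14:
            raise SingularJacobianError(
                "Jacobian is singular at the Newton iterate "
                "(possible conservation laws)"
            )
        try:
            dx = sla.solve(J, -fx)
        except sla.LinAlgError as exc:
            raise SingularJacobianError(str(exc)) from exc
        # halve the damping factor until the residual decreases
        alpha = 1.0
        while alpha >= 2.0**-8:
            x_new = x + alpha * dx
            f_new = cm.f(x_new, p, k, 0.0)
            stats.rhs_evaluations += 1
            res_new = wrms(f_new, x_new, cfg)
            if res_new < res or res_new < 1.0:
                x, fx, res = x_new, f_new, res_new
                break
            alpha /= 2.0
        else:
            raise SteadyStateFailureError(
                f"Newton line search stalled at residual {res:.3g}"
            )
    if res < 1.0:
        return x, res
    raise SteadyStateFailureError(
        f"Newton did not converge in {cfg.newton_max_iters} iterations "
        f"(residual {res:.3g})"
    )


def find_steady_state(cm: CompiledModel, p, k, x_guess, cfg: SolverConfig | None = None) -> SteadyState:
    """Newton-first steady-state search with a simulation fallback.

    On Newton failure (including a singular Jacobian, the signature of
    conservation laws), the system is simulated until the weighted-RMS
    criterion is met or t exceeds ``cfg.ss_t_max``, then polished by Newton
    when the Jacobian allows it.
    """
    if cfg is None:
        cfg = SolverConfig()
    p = np.asarray(p, dtype=float)
    k = np.asarray(k, dtype=float)
    x_guess = np.asarray(x_guess, dtype=float)
    stats = SolverStats()

    try:
        x_ss, res = _newton(cm, p, k, x_guess, cfg, stats)
        return SteadyState(x_ss=x_ss, residual_norm=res, method_used="newton", stats=stats)
    except (SingularJacobianError, SteadyStateFailureError):
        pass  # fall through to the simulation route

    # simulation fallback
    rhs = lambda t, x: cm.f(x, p, k, t)
    jac = _make_jac(cm, p, k, cfg)
    converged = lambda t, x: wrms(cm.f(x, p, k, t), x, cfg) < 1.0
    try:
        _, _, interp, t_stop = _integrate(
            rhs, jac, x_guess, 0.0, cfg.ss_t_max, cfg, [], stats, converged=converged
        )
    except IntegrationFailureError as exc:
        raise SteadyStateFailureError(
            f"steady-state simulation failed: {exc}"
        ) from exc
    x_end = (
        np.atleast_1d(interp(t_stop)).astype(float) if interp is not None else x_guess
    )
    res = wrms(cm.f(x_end, p, k, t_stop), x_end, cfg)
    if res >= 1.0:
        raise SteadyStateFailureError(
            f"no steady state up to t={cfg.ss_t_max:g} (residual {res:.3g})"
        )
    # optional Newton polish from the simulated point
    try:
        x_pol, res_pol = _newton(cm, p, k, x_end, cfg, stats)
        if res_pol < res:
            return SteadyState(
                x_ss=x_pol,
                residual_norm=res_pol,
                method_used="newton_after_simulation",
                t_reached=t_stop,
                stats=stats,
            )
    except (SingularJacobianError, SteadyStateFailureError):
        pass
    return SteadyState(
        x_ss=x_end,
        residual_norm=res,
        method_used="simulation",
        t_reached=t_stop,
        stats=stats,
    )
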