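# Methods

## Model class

odesens treats a biochemical reaction network as the ODE system

    dx/dt = f(x, p, k, t),   x(t0) = x0(p, k),
    y     = h(x, p, k),      σ = σ(p, k),

with states `x` (species concentrations), dynamic parameters `p` (the
quantities sensitivities are computed for), fixed parameters `k`
(condition-settable constants, including compartment sizes), observables `y`
and noise scales `σ`. When a model comes from reactions, the right-hand side
is assembled as `f = S·v` from the integer stoichiometric matrix `S` and the
vector of kinetic laws `v`.

### SBML subset

The importer accepts SBML Level 3 core (and Level 2 Version ≥ 4) documents
restricted to smooth ODE semantics: species, constant-size compartments,
global/local parameters, reactions with kinetic laws, assignment rules
(substituted symbolically), rate rules, initial assignments and function
definitions (expanded inline). Events, delay terms, algebraic rules and
`fast` reactions are rejected with diagnostics naming the construct, because
they break the smoothness assumptions the sensitivity machinery relies on.
Unit annotations are ignored — all values are taken at face value.

Species are stored as concentrations; `initialAmount` values are divided by
the compartment size at import, and the concentration rate of a species in a
compartment of size `V` is `(S·v)_i / V`. For unit compartments (all shipped
fixtures) this reduces to `f = S·v` exactly, which is also what the
round-trip invariant checks.

## Derivatives: partials symbolically, totals numerically

All first-order partial derivatives — `∂f/∂x` (the Jacobian `J`), `∂f/∂p`,
`∂x0/∂p`, `∂h/∂x`, `∂h/∂p`, `∂σ/∂p` — are derived **symbolically once** per
model and compiled to pure numeric evaluators. Total derivatives are never
derived symbolically; they are composed at runtime from partials by sparse
matrix multiplication and addition (e.g. `dy/dp = ∂h/∂x · sx + ∂h/∂p`). This
keeps symbolic processing linear in model size and makes the runtime cost of
a total derivative a sparse mat-mat product.

Sparse carriers use compressed-sparse-column layout with a canonical
(column, row) entry order, so repeated evaluations are bit-reproducible.
Structural zeros are detected by bounded-effort simplification (expand, then
`simplify` only for small expressions); an entry that cannot be *proven*
zero stays in the pattern — correctness over minimality. Expression
evaluation goes through `sympy.lambdify` on NumPy; the contract is purity
and ≤ 1e−12 relative agreement with direct symbolic substitution, which the
test-suite checks on random points.

## Integration

The default integrator is a variable-order, variable-step implicit
multistep (BDF) method driven step-by-step, with the analytic Jacobian used
in its Newton iterations. The `nonstiff_multistep` option maps to an
Adams-type multistep method with automatic stiffness switching (LSODA).
`linear_solver` selects the factorization inside implicit steps: `dense`
(LAPACK LU) or `sparse` (CSC + sparse LU). An `iterative` (Krylov) option is
declared in the interface but not implemented; selecting it raises
`NotSupportedError` rather than silently falling back.

Defaults: `rtol = 1e−8`, `atol = 1e−12`, `max_steps = 1e5`. Exhausting the
step budget or a step-size underflow raises `IntegrationFailureError`
carrying the failure time. Dense output over the whole span comes from the
integrator's own per-step interpolants (order-matched, C⁰ at step
boundaries); this is what the adjoint backward pass replays the forward
solution from, instead of checkpoint re-integration — at desk scale the
interpolant comfortably fits in memory, and the interpolation error is
absorbed by the 1e−4 gradient cross-check budget.

## Steady states

Steady-state search is Newton-first: damped Newton on `f(x) = 0` with the
analytic Jacobian, halving the damping factor down to 2⁻⁸ until the residual
decreases. Convergence is declared by the weighted RMS criterion

    sqrt( (1/n_x) Σ_i ( f_i / (atol·c + rtol·c·|x_i|) )² ) < 1 ,  c = ss_tol_factor (default 10),

the weighted-norm convention of the multistep solver family. A singular
Jacobian — the signature of conservation laws — or a stalled line search
triggers the simulation fallback: integrate until the criterion fires or
`t` exceeds 1e10, then polish with Newton if the Jacobian allows.
`method_used` records which path produced the result.

## Sensitivity analysis

**Forward.** The ODE is augmented with one linear system per parameter,
`ds_j/dt = J s_j + ∂f/∂p_j`, `s_j(0) = ∂x0/∂p_j`, integrated jointly with
the state. The Jacobian is evaluated once per right-hand-side call and
shared across all parameter columns. The integrator's Newton matrix uses the
block-diagonal approximation `diag(J, …, J)`: it is exact for the state
block and ignores the sensitivity-to-state coupling, which affects only the
Newton convergence rate, never the converged solution (local error control
acts on the full augmented state). Output sensitivities are assembled at
output times by the same runtime-sparse code path used everywhere else.

**Adjoint.** For a discrete-data negative log-likelihood `G = Σ_i g_i`, the
gradient is obtained from one backward integration: between datapoints
`dλ/dt = −Jᵀ λ` with `λ(T⁺) = 0`; at each datapoint time λ jumps by
`(∂g_i/∂x)ᵀ = ∂h/∂xᵀ · ∂g_i/∂y`; the quadrature `q = ∫ λᵀ (∂f/∂p) dt`
accumulates alongside, and

    ∇G = q + Σ_i ∂g_i/∂p|direct + λ(t0)ᵀ · ∂x0/∂p ,

where the direct terms flow through `∂h/∂p` and `∂σ/∂p`. Because σ is a
function of parameters only (state-dependent noise is rejected at
validation), the jumps stay linear in the residual. The backward system's
Newton matrix is the exact bordered block `[[−Jᵀ, 0], [−∂f/∂pᵀ, 0]]`.

**Steady state.** At an equilibrium with nonsingular Jacobian, the
implicit-function theorem gives `J s* = −∂f/∂p`: one factorization, `n_p`
solves, with the configured dense or sparse direct solver. A singular
Jacobian triggers a fallback that integrates the augmented forward system to
convergence (same weighted-RMS criterion on the augmented derivative); the
result is flagged with the path taken.

**Combinations.** Pre-equilibration composes with both methods: the forward
method seeds the main phase with `s*` of the pre-equilibration condition;
the adjoint method adds `λ(t0)ᵀ s*`, with `s*` obtained from the
steady-state linear solve (or its fallback). Adjoint together with
pre-simulation is not supported and raises `NotSupportedError`;
pre-equilibration is the only supported combination.

## PEtab objective

`load_petab` assembles a problem from the YAML index plus condition,
observable, measurement and parameter TSV tables, collecting *all* lint
violations into one error. Observable/noise placeholder overrides
(`observableParameter1_<id>`, `noiseParameter1_<id>`; semicolon-separated,
numeric or parameter references) are resolved symbolically at load time into
distinct observable instances, so `∂h/∂p` and `∂σ/∂p` automatically carry
the override structure. Supported noise models: normal and log-normal
(`observableTransformation: log`); per-point contribution

    g_i = ½((ȳ_i − y_i)/σ_i)² + ½ log(2π σ_i²)            (normal)

with the log-transformed analogue plus `log ȳ_i` for log-normal. Replicated
measurements are independent contributions.

After loading, the dynamic/fixed split is re-derived: dynamic `p` :=
estimated parameters (plus estimation-only parameters referenced from
formulas, e.g. noise scales), everything else `k`. Condition tables may
therefore only override fixed parameters and species initial values —
overriding an estimated parameter is a load-time error — which keeps the
gradient mapping trivial and condition-independent. Species initial
overrides must resolve to numbers; their `∂x0/∂p` rows are zeroed.
Measurements at `t = 0` use the (post-pre-equilibration/pre-simulation)
initial state without integration.

Parameter scales: estimation happens on `lin`, `log` or `log10` scale;
gradients are chain-ruled with factors 1, `p`, `p·ln 10`. Conditions are
evaluated independently and aggregated in sorted order with rows sorted by
(time, observable, value), so the reported value and gradient are
bit-identical under any table ordering — the contract that makes
parallelization over conditions safe. The objective *value* always goes
through the one plain-simulation code path, so it is bit-identical between
the forward and adjoint methods. Failing conditions either raise (default)
or map to a `+inf` objective (`on_failure="inf"`), whichever the caller's
optimizer prefers. Pre-simulation is not expressible in PEtab v1 tables; it
is exposed programmatically on `Condition.presimulation`.

## Fixture catalogue and synthetic data

The catalogue covers one failure mode each: `decay` and `linear_chain(n)`
(linear, closed forms), `conversion` (conserved total ⇒ singular Jacobian),
`synthesis_degradation` (nontrivial steady state, two-phase experiments) and
`lotka_volterra` (nonlinear, oscillatory). For every linear fixture the
closed-form solution `x(t) = e^{At} x0` (plus particular part) and its
parameter derivatives are built symbolically — matrix exponential, then
differentiation — and compiled; this oracle shares no code with the
integrator it checks, and the test-suite verifies symbolically that it
satisfies the ODE.

PEtab bundles draw synthetic measurements from a high-accuracy simulation
(`rtol = 1e−10`) at the true parameters with additive normal noise. Default
conditions: 10 time points per observable on (0, 3] (on (0, 1] for the
equilibration fixture), noise scale σ = 0.02 (0.01 for the equilibration
fixture, 0.05 for the oscillatory one, roughly 2–5 % of signal amplitude —
tight but realistic for calibrated assays); parameters estimated on log10
scale with bounds 10⁻³–10³, the convention typical of estimation benchmarks.
Tables are a deterministic, byte-identical function of the seed.

What the generator does **not** emulate: measurement dropout/missingness,
outliers or heavy-tailed noise, observation offsets/scalings to be estimated
per dataset, multi-experiment batch effects, and model misspecification.
Passing tests therefore demonstrate correctness of the numerics and of the
estimation plumbing on well-specified problems, not robustness of inference
on messy experimental data.

## Verification strategy and problem sizes

The headline checks (also recomputed by `scripts/acceptance.py`) are:
analytic-suite agreement within 10·rtol at rtol = 1e−8 over 50 time points
per fixture; pairwise forward/adjoint/central-FD gradient agreement below
1e−4 relative (components with magnitude > 1e−8, rtol = 1e−10) on four
estimation problems including pre-equilibration and estimated noise;
steady-state solves vs forward sensitivities at t = 1e6 below 1e−5 and
`s* = −A⁻¹B` on random stable 5-state linear systems to 1e−10; sparse
assembly vs dense arithmetic to 1e−12 at 100 random points per fixture;
conservation drift below 1e−8; bit-exact order invariance; and a 10-replicate
recovery study (two-parameter reversible conversion, 20 data points,
σ = 0.02) requiring the truth inside 3 Fisher standard errors in ≥ 9
replicates. These problem sizes keep the whole verification run in the
low tens of seconds on one core while still exercising every code path
(stiff steps, singular Jacobians, two-phase pipelines, noise-parameter
gradients).

## Numerical choices and edge cases

- Zero-recognition effort in sparsity detection is bounded (see above);
  patterns are conservative.
- `wrms` weights use `atol·c + rtol·c·|x_i|` with the current iterate's
  magnitudes; an empty state vector has norm 0 by convention.
- Newton damping halves down to 2⁻⁸ and requires monotone residual decrease;
  a stall is treated like a singular Jacobian (fallback to simulation).
- Degenerate simulation requests (all time points equal to t0) return the
  initial state without touching the integrator.
- FD oracle defaults: central differences with per-coordinate step
  `1e−5 · max(|p_j|, 1)`.
- Seeds are explicit arguments everywhere (fixture generation, CLI); no
  global random state is consulted.

## Known limitations

- No events, delays, algebraic rules or DAEs; no non-constant compartments.
- No Krylov linear solvers; no second-order adjoints/Hessians.
- Adjoint + pre-simulation is unsupported (raises); adjoint +
  pre-equilibration is the one supported combination.
- σ may depend on parameters but not on states.
- PEtab v2, priors, steady-state (t = ∞) measurements and visualization
  tables are out of scope.
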