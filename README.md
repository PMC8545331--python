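# odesens

Simulation and sensitivity analysis for ordinary-differential-equation models
of biochemical reaction networks, aimed at gradient-based parameter
estimation: import an SBML model, simulate it stiffly with analytic
Jacobians, and compute derivatives of states, outputs and objective
functions with respect to parameters by **forward**, **adjoint** and
**steady-state** methods — including the negative log-likelihood and
gradient of PEtab-style estimation problems with pre-equilibration and
pre-simulation phases.

## Who this is for

Systems-biology modellers calibrating ODE models against time-course data.
Optimizers and samplers need many accurate gradient evaluations; finite
differences are slow and noisy, and hand-derived sensitivities are
error-prone. odesens derives everything symbolically from the model
structure and exposes objective + gradient as plain functions, leaving the
choice of optimizer downstream.

## The model and its derivatives

A reaction network is represented as

    dx/dt = f(x, p, k, t) = S·v(x, p, k),   x(0) = x0(p, k),
    y = h(x, p, k),   σ = σ(p, k),

with stoichiometric matrix `S`, kinetic laws `v`, dynamic parameters `p` and
condition-specific constants `k`. Only *partial* derivatives (`∂f/∂x`,
`∂f/∂p`, `∂x0/∂p`, `∂h/∂x`, `∂h/∂p`, `∂σ/∂p`) are derived symbolically;
total derivatives such as `dy/dp = ∂h/∂x·sx + ∂h/∂p` are assembled at
runtime by sparse matrix products. Gradients of a data likelihood
`G = Σ_i g_i(y(t_i), σ)` come either from forward sensitivities
(`ds_j/dt = J s_j + ∂f/∂p_j`, cost ∝ #parameters) or from one backward
adjoint integration (`dλ/dt = −Jᵀλ` with jumps `∂g_i/∂x` at the data,
`∇G = ∫ λᵀ∂f/∂p dt + Σ_i ∂g_i/∂p + λ(0)ᵀ∂x0/∂p`, cost nearly independent of
#parameters). At equilibria, `J s* = −∂f/∂p` gives steady-state
sensitivities from one factorization; singular Jacobians (conservation
laws) fall back to simulating the augmented system.

## Worked example

Generate a seeded two-parameter estimation problem (reversible conversion
A ⇌ B, 20 noisy measurements), then evaluate the objective and its gradient
by both sensitivity methods:

```python
import numpy as np
from odesens import (FixtureSpec, generate_fixture, load_petab,
                     objective_and_gradient)

paths = generate_fixture(
    FixtureSpec(name="conversion", petab=True, sigma=0.02),
    seed=1000, outdir="example",
)
problem = load_petab(paths["yaml"])
theta = problem.nominal_estimated()          # log10 scale: [0.0, 0.301...]

forward = objective_and_gradient(problem, theta, "forward")
adjoint = objective_and_gradient(problem, theta, "adjoint")
print("nll      :", forward.value)
print("grad fwd :", forward.gradient)
print("grad adj :", adjoint.gradient)
```

Output:

```
nll      : -50.1347530022164
grad fwd : [ 84.61471565 -76.51177027]
grad adj : [ 84.61459693 -76.51167067]
```

The objective value is the summed negative log-likelihood (negative here
because σ = 0.02 makes the Gaussian densities large); the gradient is on the
log10 estimation scale, and the two methods agree to ~1e−6 relative — the
adjoint result needed one backward integration instead of one forward
system per parameter. A quasi-Newton optimizer driven by this function
recovers the true rates within statistical error (the recovery study in the
test-suite checks exactly that).

The same functionality is available from a shell:

```sh
odesens make-fixture conversion --petab --seed 1000 --outdir example
odesens gradient example/problem.yaml --method adjoint
odesens check-gradient example/problem.yaml --method both
odesens simulate example/conversion.xml --times 0,1,2,3 --set k1=2.0
```

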