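# momentfit

Parameter inference for stochastic biochemical reaction networks by **moment
fitting**: instead of comparing only mean concentration traces with model
predictions, the rate parameters are adjusted so that the model also fits the
*higher sample moments* (variances, covariances) computed from repeated,
possibly partial, observations of the process.

The package is aimed at systems biologists and methods developers who work
with discrete-state stochastic kinetics (chemical master equation / Gillespie
models) and need to recover rate constants from ensemble time-series data —
for example, repeated single-cell molecule-count measurements.

## The method

A well-mixed network of `v` reactions over `u` species with state `x` (copy
numbers), stoichiometric matrix `S` and propensities `h_j(x, c)` defines a
Markov jump process governed by the chemical master equation. From the master
equation one derives closed ODE systems for approximate moments
`ν̃(t; c)` up to order `n`:

* **exact equations** for mean `m` and covariance `V` when every propensity is
  affine in `x`:
  `dm/dt = S h(m)`, `dV/dt = S J_h V + V J_hᵀ Sᵀ + S diag(h(m)) Sᵀ`;
* **normal closure** (third central moment set to zero) for one-dimensional
  state spaces, from the Fokker–Planck drift `A(x) = Σ s_j h_j` and diffusion
  `B(x) = Σ s_j² h_j`;
* the **linear noise approximation** (LNA): the mean solves the macroscopic
  rate equation `dΦ/dt = S h(Φ)` and the covariance the Lyapunov equation
  `dV/dt = J V + V Jᵀ + S diag(h(Φ)) Sᵀ` with `J = S ∂h/∂x(Φ)`.

Given `N` replicate observations of `d ≤ u` components at times `t_1 … t_K`,
per-time sample moments `ν̂(t_k)` (mean, covariance) are compared with the
observed block of the model prediction through the weighted cost

    Δ_n(c) = Σ_{i=1..n} w_i Σ_k ‖ ν̂_i(t_k) − ν̃_i(t_k; c) ‖²

minimized over `c > 0` by trust-region nonlinear least squares or an
adjoint-gradient quasi-Newton driver; exact cost gradients come from one
backward adjoint ODE solve with residual jump conditions at the observation
times. A Metropolis random walk with Gamma priors provides the Bayesian
route, and Hessian eigen-decompositions (Gauss–Newton or finite differences,
linear or log parameter scale) quantify *parameter sloppiness* — near-zero
curvature directions along which the data do not constrain the parameters.

The point of fitting moments beyond the mean: mean-only costs can be exactly
flat along parameter combinations (for the linear birth–death process the
mean depends on `c1 − c2` only), and adding the variance residual restores a
unique, well-conditioned minimum.

## Worked example

Simulate 10,000 birth–death trajectories (`X → 2X` at rate `c1·x`, `X → ∅` at
rate `c2·x`, truth `c = (0.1, 0.2)`, `x0 = 30`), observe them at 20 time
points on `[0, 10]`, and fit from the distant initial guess `(0.5, 0.7)`:

```python
import numpy as np
from momentfit import (CostSpec, ObservationOperator, builtin_model,
                       compute_sample_moments, equidistant_times,
                       exact_moment_system, fit_parameters, hessian,
                       simulate_ensemble, sloppiness_report)

net = builtin_model("birth_death")
c_true = net.default_params                 # (0.1, 0.2)
obs = ObservationOperator((0,), equidistant_times(10.0, 20))

data = simulate_ensemble(net, c_true, net.x0, obs, n_replicates=10_000, seed=1)
moments = compute_sample_moments(data)      # per-time sample mean and variance
system = exact_moment_system(net)           # closed mean/variance ODEs

for order in (1, 2):
    spec = CostSpec(system, obs, moments, net.x0, order=order)
    fit = fit_parameters(spec, c_init=np.array([0.5, 0.7]), true_params=c_true)
    print(f"order {order}: c_hat = {np.round(fit.c_hat, 4)}, "
          f"rel. errors = {np.round(100 * fit.rel_errors, 2)} %, "
          f"{fit.n_iterations} iterations")

report = sloppiness_report(hessian(CostSpec(system, obs, moments, net.x0, order=1),
                                   c_true))
print("order-1 Hessian eigenvalues:", report.eigenvalues)
print("sloppy direction:", np.round(report.sloppy_directions[:, 0], 4))
```

Output:

```
order 1: c_hat = [0.6353 0.7355], rel. errors = [535.32 267.74] %, 14 iterations
order 2: c_hat = [0.1004 0.1995], rel. errors = [0.37 0.23] %, 13 iterations
order-1 Hessian eigenvalues: [6.06342285e+05 3.23052518e-09]
sloppy direction: [-0.7071 -0.7071]
```

The mean-only (order-1) fit reproduces the mean data perfectly yet lands far
from the truth: any `(c1 + s, c2 + s)` explains the means equally well, which
is exactly the zero Hessian eigenvalue with eigenvector `(1, 1)/√2`. Fitting
mean *and* variance (order 2) recovers both rates to a fraction of a percent
from the same data.

## Command line

The `momentfit` console script exposes the pipeline as subcommands —
`simulate` (SSA ensembles to CSV), `moments`, `fit`, `mcmc`, `sloppy`, and
`casestudy {birth_death,dimerisation,p53}` for the three end-to-end
simulate-then-recover experiments. All artifacts are plain CSV/JSON and embed
the seed and package version. `momentfit COMMAND --help` shows the options.

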