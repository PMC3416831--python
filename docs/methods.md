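# Methods

This note records the models implemented in `momentfit`, the default study
conditions of the built-in experiments, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Process model and simulator

A reaction network is a continuous-time Markov jump process on non-negative
integer copy-number vectors: reaction `j` fires at propensity `h_j(x, c)` and
shifts the state by the `j`-th column of the stoichiometric matrix `S`.
Propensities are stored as symbolic expressions (sympy); mass-action laws use
the stochastic convention with combinatorial counting, e.g. `c·x(x−1)/2` for
`2X → ·`, so a propensity is automatically zero whenever reactant copies are
insufficient and no negative state is reachable.

`simulate_ssa` implements the exact direct (Gillespie) method: exponential
waiting times with rate equal to the total propensity, reaction choice
proportional to the individual propensities. A realization ends at the time
horizon or in an absorbing state (total propensity zero); observation times
after absorption report the absorbing state. Sampling a trajectory at a time
point uses the **right-continuous** convention (state after the last jump at
or before the query time); the process is cadlag and the choice at exact jump
times is stated here because it is a convention, not a theorem.

`simulate_ensemble` draws each replicate from its own substream spawned from
one master `SeedSequence`, so individual replicates are reproducible in
isolation and results do not depend on execution order. Reaction identities
and jump times are kept internal; inference only ever sees counts at the
observation grid, which is what realistic snapshot measurements provide.

What the generator does *not* emulate: measurement noise on top of counts,
extrinsic (cell-to-cell parameter) variability, partial molecule detection,
and non-stationary volume effects. Passing tests therefore demonstrate
correctness of the inference machinery under the intrinsic-noise model, not
robustness to instrument noise or model misspecification.

## Moment systems

The stacked moment state is `(m_1 … m_u, V_packed)` with the covariance
packed row-major over the upper triangle — `(0,0), (0,1), …, (1,1), …` — a
single convention shared by every module. All three constructions are built
symbolically from the propensity expressions and compiled (with exact
state- and parameter-Jacobians) for the integrator and the adjoint solver:

* **Exact affine equations.** For propensities affine in `x`,
  `E[h(X)] = h(E X)` and the mean/covariance equations close without
  approximation. Requesting this system for a nonlinear network raises a
  not-applicable error naming the offending reaction.
* **Normal closure (1-D).** From the Fokker–Planck drift
  `A(x) = Σ_j s_j h_j(x)` and diffusion `B(x) = Σ_j s_j² h_j(x)`, Taylor
  expansion about the mean with the third central moment set to zero gives
  `dm/dt = A(m) + ½A″(m)v` and `dv/dt = 2A′(m)v + B(m) + ½B″(m)v`.
  For affine `A, B` the correction terms vanish and the system coincides with
  the exact one (tested). The normal closure is the only closure shipped;
  moment order is capped at 2 throughout, though the state layout is
  order-generic.
* **Linear noise approximation.** Mean = macroscopic rate equation;
  covariance = Lyapunov dynamics driven by the Jacobian of the macroscopic
  drift and the fluctuation source `S diag(h(Φ)) Sᵀ`. Valid for any
  differentiable propensities; for affine networks it coincides with the
  exact system.

Deterministic initial data give mean `x0` and zero initial covariance.
Integration uses LSODA with analytic Jacobian at `rtol 1e-8 / atol 1e-10` —
deliberately tighter than fitting requires, so integration error never
masquerades as model error. Integration failure raises an error carrying the
parameter vector; the fitting driver treats it as a rejected step.

Two oracles accompany the systems: the closed-form birth–death solution
`m(t) = x0 e^{(c1−c2)t}`,
`v(t) = x0 (c1+c2)/(c1−c2) · e^{(c1−c2)t}(e^{(c1−c2)t} − 1)` (continuous
limit `2 c1 x0 t` at `c1 = c2`, evaluated via `expm1` for stability), and a
truncated chemical-master-equation integrator on a capped lattice that
reports exact moments of the truncated distribution together with the leaked
probability mass.

## Sample moments

Per-time mean and covariance of the observed components across replicates;
covariance uses the unbiased divisor `N−1` by default with a `ddof=0` switch
(both conventions are defensible; the default is documented rather than
argued). With `N ≤ d` the plain empirical covariance is rank-deficient and
the function refuses with advice to increase `N` — shrinkage estimation is
out of scope.

## Cost functions, likelihood, gradients

The order-`n` cost is a weighted sum over observation times of squared
residuals between sample and predicted moments of the observed block; the
covariance block enters through the packed upper triangle, each distinct
entry once. The residual vector is ordered mean-block-first, time-major, so
`cost = ‖residuals‖²` holds to machine precision and Jacobians align
bit-stably. Default weights are `w1 = w2 = 1`; they are configurable because
count variances can be orders of magnitude larger (and noisier) than count
means, and the sensible scale balance is problem-dependent — the p53 study
uses `w2 = 1e-3` for exactly this reason.

The mean-only Gaussian likelihood scores the per-time sample mean under
`Normal(m(t_k; c), v(t_k; c)/N)`. Whether such a likelihood should use
per-replicate data or per-time sample means is a modelling choice; the
sample-mean form is implemented and isolated in one function so it can be
swapped. It intentionally never compares the sample variance with the model
variance, which is what produces its boundary-seeking failure mode along
mean-preserving parameter ridges.

Gradients: the cost is a functional of the moment-ODE solution evaluated at
discrete times, so its exact gradient follows from one backward adjoint
solve, `dλ/dt = −(∂f/∂z)ᵀ λ` with jumps `2 Pᵀ W r_k` at each observation
time (impulse forcing — the discrete-residual analogue), plus the quadrature
`∫ (∂f/∂c)ᵀ λ dt`. The forward solution is reused through dense output, and
backward tolerances match the forward ones. A central finite-difference
oracle cross-validates the adjoint on every built-in model in the tests.

### Finite-difference step sizes

Steps were chosen from a noise/truncation analysis against the integrator
error (relative solution error ≈ 1e-8 · scale): gradient oracle rel. step
`1e-4`; residual-Jacobian (Gauss–Newton Hessian, least-squares `diff_step`)
rel. step `1e-3`–`1e-4`; second-difference Hessian rel. step `1e-2`. Smaller
steps would amplify integration noise, larger ones incur visible truncation
error.

## Fitting and MCMC

`fit_parameters` wraps scipy's trust-region-reflective nonlinear least
squares on the residual vector (finite-difference Jacobian, positivity via a
`1e-12` lower bound, `xtol = ftol = gtol = 1e-10`, at most 200 outer
iterations; outer iterations are counted as Jacobian evaluations). A
log-parameter option optimizes `θ = log c` instead — the right choice when
rates span orders of magnitude. The alternative `lbfgs_adjoint` driver feeds
the exact adjoint gradient to L-BFGS-B; because quasi-Newton convergence
rates degrade with the condition number of the Hessian, this driver is also
the one used for the dimerisation efficiency comparison, where trust-region
iteration counts turn out to be nearly insensitive to the conditioning
difference.

`mcmc_metropolis` is a symmetric Gaussian random walk over the rates with
independent Gamma(shape, rate) priors; proposals outside the positive orthant
are rejected (zero prior support), a failing likelihood evaluation counts as
a rejection with a warning, and chains are bit-reproducible given the seed.
Defaults: 50,000 steps, 10,000 burn-in, proposal sd 5% of the initial point —
all configurable, since sensible values are problem-specific.

## Sloppiness analysis

`hessian` provides Gauss–Newton (`2 JᵀJ`, exact at zero-residual minimizers)
and central-second-difference Hessians, in linear or log parameter scale
(log = relative parameter changes; at a stationary point
`H_log = diag(c) H diag(c)`, tested). `sloppiness_report` returns the
descending eigen-spectrum; eigenvalues below `1e-10` of the largest are
classified as sloppy directions and the condition number is then reported as
infinite. The evaluation point is explicit and recorded, since Hessians at
the truth and at a minimizer answer different questions. Line and grid scans
support level-set plots of the cost landscape.

## Built-in models and default study conditions

All experiments are self-consistent simulate-then-recover studies; the
defaults below are the package's study conditions, chosen once at design
time.

* **Linear birth–death** (`X → 2X` at `c1 x`, `X → ∅` at `c2 x`):
  `c* = (0.1, 0.2)`, `x0 = 30`, 20 equidistant observation times on
  `(0, 10]`, `N = 10,000` replicates, fitting initial guess `(0.5, 0.7)`.
  The decay/extinction regime exercises absorbing-state handling; the mean
  depends on `c1 − c2` only, making this the canonical ridge example.
* **Dimerisation** (`2X → D` at `c1 x(x−1)/2`, `D → 2X` written in the
  conservation-reduced monomer form `h2 = c2 (M − x)/2`, stoichiometry
  `(−2, +2)`): `c* = (1.66e-3, 0.2)` (the classic stochastic-kinetics
  dimerisation constants), `M = 301 = x0`, 16 times on `(0, 8]`, `N = 1000`,
  initial guess `2 c*`, fits with the adjoint-gradient driver. `M` is a model
  constant, not a fitted parameter; parity of `x` is conserved.
* **p53/Mdm2 feedback** (p53 `x`, precursor `y0`, Mdm2 `y`; constitutive
  production `b_x`, basal degradation `a_x x`, Mdm2-mediated saturating
  degradation `a_k y x/(x + k)`, precursor production `b_y x`, maturation
  `a_0 y0`, Mdm2 decay `a_y y`):
  `c* = (90, 0.02, 2.0, 30, 0.2, 0.5, 0.5)`, `x0 = (20, 5, 10)`, 12 times on
  `(0, 24]` hours, `N = 1000`, LNA predictions, log-scale fits from
  `1.3 c*`. The defaults put the loop in the damped-oscillation regime that
  is the experimental hallmark of this system; the oscillatory transient is
  what makes the scalar p53 moments informative about the unobserved Mdm2
  chain. The partial-observation study compares fitting the means of p53 and
  Mdm2 (order 1) against fitting mean and variance of p53 alone (order 2,
  `w = (1, 1e-3)`).

The MCMC study runs the mean-only likelihood on birth–death data with
`Gamma(2, 2/c*_i)` priors (prior mean at the truth, generously wide) and
reports the posterior spread of `c1 + c2` versus `c1 − c2`.

## Known limitations

* The order-2 single-observable p53 fit and the two-observable mean fit
  deliver estimates of the same quality under the default conditions
  (`N = 1000`); which of the two has the smaller maximal per-component error
  varies from ensemble to ensemble. The variance data demonstrably
  substitutes for the second observed component (and constrains the
  saturation constant `k` better in most ensembles), but a strict uniform
  ordering of the two protocols should not be expected at this sample size.
* Moment equations above order 2, non-normal closures, generalized least
  squares with moment cross-covariances, f-divergence costs, sparsity
  penalties and Kalman-type filters are out of scope.
* The truncated-CME integrator is an oracle for small state spaces, not an
  inference engine; it refuses lattices beyond ~2·10⁵ states.
* The Metropolis sampler is deliberately plain (no adaptation); with a
  sharply ridged target its acceptance rate is low, which is part of the
  failure mode being demonstrated, not an implementation target.
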