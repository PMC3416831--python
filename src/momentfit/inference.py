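"""Deterministic least-squares fitting and Metropolis random-walk MCMC.

``fit_parameters`` minimizes the moment-residual vector with scipy's
trust-region-reflective nonlinear least squares (finite-difference residual
Jacobian by default), with positivity enforced by bounds; an L-BFGS-B driver
fed by the exact adjoint gradient is available as an alternative.
``mcmc_metropolis`` runs a symmetric Gaussian random walk over the rate
parameters with independent Gamma priors; proposals leaving the positive
orthant are rejected (zero prior support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .adjoint import cost_gradient_adjoint
from .costs import CostSpec, residual_length, residuals
from .errors import CostEvaluationError, SolverError, ValidationError

__all__ = ["FitResult", "Chain", "GammaPrior", "fit_parameters",
           "mcmc_metropolis", "chain_summary"]

_FAILED_RESIDUAL = 1e8   # rejected-step sentinel for solver failures


@dataclass
class FitResult:
    c_hat: np.ndarray
    iterates: np.ndarray          # accepted (cost-decreasing) parameter vectors
    cost_trace: np.ndarray        # cost at each accepted iterate, non-increasing
    n_iterations: int             # outer trust-region iterations (Jacobian evals)
    n_evaluations: int
    termination: str
    success: bool
    cost: float
    rel_errors: np.ndarray | None = None


def fit_parameters(spec: CostSpec, c_init, *, method="trf", log_scale=False,
                   diff_step=1e-4, xtol=1e-10, ftol=1e-10, gtol=1e-10,
                   max_iterations=200, bound_eps=1e-12, true_params=None):
    """Minimize the moment-fitting cost from ``c_init``.

    Deterministic given (spec, c_init, options).  ``log_scale`` optimizes over
    theta = log c instead (positivity then holds by construction).
    """
    c_init = np.asarray(c_init, dtype=float)
    if np.any(c_init <= 0):
        raise ValidationError("c_init must be strictly positive")
    m = residual_length(spec)
    trace_c, trace_cost = [], []

    def to_c(v):
        return np.exp(v) if log_scale else v

    def fun(v):
        c = to_c(v)
        try:
            r = residuals(c, spec)
        except SolverError as exc:
            warnings.warn(f"cost evaluation rejected: {exc}", RuntimeWarning)
            return np.full(m, _FAILED_RESIDUAL)
        trace_c.append(np.array(c))
        trace_cost.append(float(r @ r))
        return r

    r0 = fun(np.log(c_init) if log_scale else c_init)
    if not np.all(np.isfinite(r0)) or trace_cost[-1] >= _FAILED_RESIDUAL ** 2 * m:
        raise CostEvaluationError("cost is not finite at the initial guess")

    if method == "trf":
        bounds = ((-np.inf, np.inf) if log_scale
                  else (np.full_like(c_init, bound_eps), np.full_like(c_init, np.inf)))
        res = optimize.least_squares(
            fun, np.log(c_init) if log_scale else c_init, method="trf",
            bounds=bounds, diff_step=diff_step, xtol=xtol, ftol=ftol, gtol=gtol,
            max_nfev=max_iterations * (len(c_init) + 1))
        c_hat = to_c(res.x)
        n_iter = int(res.njev) if res.njev is not None else int(res.nfev)
        term, success, final_cost = res.message, bool(res.success), 2 * float(res.cost)
    elif method == "lbfgs_adjoint":
        def fg(v):
            c = to_c(v)
            try:
                g = cost_gradient_adjoint(c, spec)
            except SolverError as exc:
                warnings.warn(f"cost evaluation rejected: {exc}", RuntimeWarning)
                return _FAILED_RESIDUAL, np.zeros_like(v)
            trace_c.append(np.array(c))
            trace_cost.append(g.cost)
            grad = g.gradient * c if log_scale else g.gradient
            return g.cost, grad
        lb = None if log_scale else [(bound_eps, None)] * len(c_init)
        res = optimize.minimize(fg, np.log(c_init) if log_scale else c_init,
                                jac=True, method="L-BFGS-B", bounds=lb,
                                options={"maxiter": max_iterations,
                                         "ftol": ftol, "gtol": gtol})
        c_hat = to_c(res.x)
        n_iter = int(res.nit)
        term, success, final_cost = str(res.message), bool(res.success), float(res.fun)
    else:
        raise ValidationError(f"unknown fit method '{method}'")

    # accepted iterates: evaluations that improved on the best cost so far
    it_c, it_cost, best = [], [], np.inf
    for cv, fv in zip(trace_c, trace_cost):
        if fv < best:
            best = fv
            it_c.append(cv)
            it_cost.append(fv)
    rel = None
    if true_params is not None:
        tp = np.asarray(true_params, dtype=float)
        rel = np.abs(c_hat - tp) / np.abs(tp)
    return FitResult(c_hat=np.asarray(c_hat), iterates=np.asarray(it_c),
                     cost_trace=np.asarray(it_cost), n_iterations=n_iter,
                     n_evaluations=len(trace_c), termination=term,
                     success=success, cost=final_cost, rel_errors=rel)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior: mean = shape/rate, variance = shape/rate^2."""

    shape: float
    rate: float

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        a, b = self.shape, self.rate
        return a * np.log(b) - gammaln(a) + (a - 1) * np.log(x) - b * x

    @property
    def mean(self):
        return self.shape / self.rate

    @property
    def var(self):
        return self.shape / self.rate ** 2


@dataclass
class Chain:
    samples: np.ndarray           # n_steps x n_params, positive
    log_target_trace: np.ndarray
    acceptance_rate: float
    burn_in: int
    seed: int
    priors: tuple
    proposal_sd: np.ndarray
    param_names: tuple = ()

    @property
    def samples_post(self):
        return self.samples[self.burn_in:]


def mcmc_metropolis(log_target, priors, c_init, n_steps=50_000,
                    proposal_sd=None, burn_in=10_000, seed=0):
    """Metropolis random walk with Gaussian innovations and Gamma priors.

    ``log_target`` is the log-likelihood (or None for prior-only sampling);
    the target is log_target + sum of prior log-densities.  Accept with
    probability min(1, exp(delta log posterior)); a failing likelihood
    evaluation at a proposal counts as a rejection.
    """
    c_init = np.asarray(c_init, dtype=float)
    p = len(c_init)
    priors = tuple(pr if isinstance(pr, GammaPrior) else GammaPrior(*pr)
                   for pr in priors)
    if len(priors) != p:
        raise ValidationError("one prior per parameter required")
    if not (0 <= burn_in < n_steps):
        raise ValidationError("need n_steps > burn_in >= 0")
    if np.any(c_init <= 0):
        raise ValidationError("c_init must be in the positive orthant")
    if proposal_sd is None:
        proposal_sd = 0.05 * c_init
    proposal_sd = np.broadcast_to(np.asarray(proposal_sd, dtype=float), (p,)).copy()
    if np.any(proposal_sd <= 0):
        raise ValidationError("proposal_sd must be positive")

    def logpost(c):
        lp = sum(pr.logpdf(v) for pr, v in zip(priors, c))
        if not np.isfinite(lp):
            return -np.inf
        if log_target is not None:
            lp += log_target(c)
        return lp

    rng = np.random.default_rng(seed)
    c = c_init.copy()
    lp = logpost(c)
    if not np.isfinite(lp):
        raise ValidationError("posterior is zero at c_init")
    samples = np.empty((n_steps, p))
    trace = np.empty(n_steps)
    n_accept = 0
    for step in range(n_steps):
        prop = c + proposal_sd * rng.standard_normal(p)
        if np.all(prop > 0):
            try:
                lp_prop = logpost(prop)
            except (SolverError, CostEvaluationError) as exc:
                warnings.warn(f"proposal rejected (target failure): {exc}",
                              RuntimeWarning)
                lp_prop = -np.inf
            if np.log(rng.random()) < lp_prop - lp:
                c, lp = prop, lp_prop
                n_accept += 1
        samples[step] = c
        trace[step] = lp
    return Chain(samples=samples, log_target_trace=trace,
                 acceptance_rate=n_accept / n_steps, burn_in=burn_in,
                 seed=int(seed), priors=priors, proposal_sd=proposal_sd)


def chain_summary(chain: Chain, bins=50, combos=None, thin=1,
                  quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)):
    """Marginal statistics and fixed-bin histograms, post burn-in.

    ``combos`` maps a label to a coefficient vector for linear combinations
    such as c1 - c2 or c1 + c2.
    """
    s = chain.samples_post[::thin]
    if len(s) == 0:
        raise ValidationError("chain is empty after burn-in")
    out = {}
    columns = {f"c{i+1}": s[:, i] for i in range(s.shape[1])}
    if chain.param_names:
        columns = {name: s[:, i] for i, name in enumerate(chain.param_names)}
    for label, coeffs in (combos or {}).items():
        columns[label] = s @ np.asarray(coeffs, dtype=float)
    for label, x in columns.items():
        counts, edges = np.histogram(x, bins=bins)
        out[label] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "quantiles": {str(q): float(np.quantile(x, q)) for q in quantiles},
            "hist_counts": counts.tolist(),
            "hist_edges": edges.tolist(),
        }
    return out
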