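"""End-to-end simulate-then-recover experiments for the built-in models.

Each study fixes its own protocol (true parameters, initial state,
observation grid, replicate count, initial guess) as the package's default
study conditions, generates ensemble data by exact SSA, fits the rate
parameters with mean-only (order 1) and mean+covariance (order 2) costs and
reports accuracy, iteration counts and Hessian conditioning.  These functions
back the ``casestudy`` CLI subcommand and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .costs import CostSpec, cost, log_likelihood_mean_only
from .inference import GammaPrior, chain_summary, fit_parameters, mcmc_metropolis
from .moment_systems import (birth_death_analytic, exact_moment_system,
                             lna_system, normal_closure_1d)
from .networks import ObservationOperator, builtin_model, equidistant_times
from .sample_moments import compute_sample_moments
from .sloppiness import hessian, sloppiness_report
from .ssa import simulate_ensemble

__all__ = ["birth_death_study", "dimerisation_study", "p53_study",
           "birth_death_mcmc_study", "BD_PROTOCOL", "DIMER_PROTOCOL",
           "P53_PROTOCOL"]

# default study conditions (observation windows, replicate counts, initial
# guesses); see docs/methods.md for the rationale behind each choice
BD_PROTOCOL = dict(t_end=10.0, n_times=20, n_replicates=10_000,
                   c_init=(0.5, 0.7))
DIMER_PROTOCOL = dict(t_end=8.0, n_times=16, n_replicates=1_000,
                      c_init_factor=2.0)
P53_PROTOCOL = dict(t_end=24.0, n_times=12, n_replicates=1_000,
                    c_init_factor=1.3, var_weight=1e-3)


def _fit_pair(system, obs_by_order, data_by_order, x0, c_init, c_true,
              method="trf"):
    """Fit with order-1 and order-2 costs from the same initial guess."""
    out = {}
    for order in (1, 2):
        spec = CostSpec(system, obs_by_order[order], data_by_order[order], x0,
                        order=order)
        out[order] = fit_parameters(spec, c_init, method=method,
                                    true_params=c_true)
    return out


def birth_death_study(seed, n_replicates=None, t_end=None, n_times=None,
                      c_init=None):
    """Linear birth-death: mean-only non-identifiability vs moment fitting.

    The analytic mean x0 exp((c1-c2) t) depends on the parameters only through
    their difference, so the order-1 cost has an exact flat ridge along
    (1, 1); adding the variance residual restores identifiability.
    """
    proto = dict(BD_PROTOCOL)
    for key, val in (("n_replicates", n_replicates), ("t_end", t_end),
                     ("n_times", n_times), ("c_init", c_init)):
        if val is not None:
            proto[key] = val
    net = builtin_model("birth_death")
    c_true, x0 = net.default_params, net.x0
    obs = ObservationOperator((0,), equidistant_times(proto["t_end"], proto["n_times"]))
    data = simulate_ensemble(net, c_true, x0, obs, proto["n_replicates"], seed)
    moments = compute_sample_moments(data)
    system = exact_moment_system(net)
    fits = _fit_pair(system, {1: obs, 2: obs}, {1: moments, 2: moments},
                     x0, np.asarray(proto["c_init"]), c_true)
    diff_true = c_true[0] - c_true[1]
    return {
        "net": net, "obs": obs, "data": data, "moments": moments,
        "system": system, "c_true": c_true, "c_init": np.asarray(proto["c_init"]),
        "fit_n1": fits[1], "fit_n2": fits[2],
        "diff_rel_err_n1": abs((fits[1].c_hat[0] - fits[1].c_hat[1] - diff_true)
                               / diff_true),
        "diff_rel_err_n2": abs((fits[2].c_hat[0] - fits[2].c_hat[1] - diff_true)
                               / diff_true),
    }


def dimerisation_study(seed, n_replicates=None, t_end=None, n_times=None,
                       c_init_factor=None):
    """Dimerisation kinetics: moment fitting as an optimization accelerator.

    Both costs identify the parameters here; the comparison is the number of
    outer iterations of the adjoint-gradient quasi-Newton driver and the
    Hessian conditioning (log scale, since c1 and c2 differ by two orders of
    magnitude) at the minimizer.
    """
    proto = dict(DIMER_PROTOCOL)
    for key, val in (("n_replicates", n_replicates), ("t_end", t_end),
                     ("n_times", n_times), ("c_init_factor", c_init_factor)):
        if val is not None:
            proto[key] = val
    net = builtin_model("dimerisation")
    c_true, x0 = net.default_params, net.x0
    obs = ObservationOperator((0,), equidistant_times(proto["t_end"], proto["n_times"]))
    data = simulate_ensemble(net, c_true, x0, obs, proto["n_replicates"], seed)
    moments = compute_sample_moments(data)
    system = normal_closure_1d(net)
    c_init = proto["c_init_factor"] * c_true
    fits = _fit_pair(system, {1: obs, 2: obs}, {1: moments, 2: moments},
                     x0, c_init, c_true, method="lbfgs_adjoint")
    # conditioning of both costs at the order-2 minimizer, relative scale
    reports = {}
    for order in (1, 2):
        spec = CostSpec(system, obs, moments, x0, order=order)
        H = hessian(spec, fits[2].c_hat, method="gauss_newton", scale="log")
        reports[order] = sloppiness_report(H, scale="log",
                                           evaluation_point=fits[2].c_hat)
    return {
        "net": net, "obs": obs, "data": data, "moments": moments,
        "system": system, "c_true": c_true, "c_init": c_init,
        "fit_n1": fits[1], "fit_n2": fits[2],
        "report_n1": reports[1], "report_n2": reports[2],
    }


def p53_study(seed, n_replicates=None, t_end=None, n_times=None,
              c_init_factor=None, var_weight=None):
    """p53/Mdm2 feedback under partial observation, LNA predictions.

    Compares fitting from the means of two observed components (p53 and Mdm2)
    against fitting from mean and variance of p53 alone.  Both fits run in
    log-parameter scale (the rates span more than three orders of magnitude);
    the variance block of the order-2 cost carries weight ``var_weight`` so
    that count variances, whose absolute sampling noise is much larger than
    that of count means, do not swamp the mean residuals.
    """
    proto = dict(P53_PROTOCOL)
    for key, val in (("n_replicates", n_replicates), ("t_end", t_end),
                     ("n_times", n_times), ("c_init_factor", c_init_factor),
                     ("var_weight", var_weight)):
        if val is not None:
            proto[key] = val
    net = builtin_model("p53")
    c_true, x0 = net.default_params, net.x0
    times = equidistant_times(proto["t_end"], proto["n_times"])
    obs_two = ObservationOperator((0, 2), times)     # p53 and mature Mdm2
    obs_one = ObservationOperator((0,), times)       # p53 only
    data = simulate_ensemble(net, c_true, x0,
                             ObservationOperator((0, 1, 2), times),
                             proto["n_replicates"], seed)
    system = lna_system(net)
    c_init = proto["c_init_factor"] * c_true
    from .ssa import DataTensor
    m_two = compute_sample_moments(
        DataTensor(data.values[:, :, [0, 2]], times, (0, 2)))
    m_one = compute_sample_moments(
        DataTensor(data.values[:, :, [0]], times, (0,)))
    fit_means2 = fit_parameters(CostSpec(system, obs_two, m_two, x0, order=1),
                                c_init, log_scale=True, true_params=c_true)
    fit_mv1 = fit_parameters(
        CostSpec(system, obs_one, m_one, x0, order=2,
                 weights=(1.0, proto["var_weight"])),
        c_init, log_scale=True, true_params=c_true)
    return {
        "net": net, "data": data, "system": system,
        "c_true": c_true, "c_init": c_init,
        "fit_means_two_observed": fit_means2,
        "fit_meanvar_one_observed": fit_mv1,
        "max_rel_err_means_two_observed": float(np.max(fit_means2.rel_errors)),
        "max_rel_err_meanvar_one_observed": float(np.max(fit_mv1.rel_errors)),
    }


def birth_death_mcmc_study(seed, n_replicates=10_000, t_end=10.0, n_times=20,
                           n_steps=50_000, burn_in=10_000,
                           prior_shape=2.0):
    """Metropolis random walk with the mean-only likelihood on birth-death data.

    The likelihood compares the sample mean with Normal(m(t;c), v(t;c)/N) and
    never sees the sample variance, so the posterior constrains c1 - c2 but
    lets c1 + c2 drift -- the classic ridge failure mode.  Returns the chain
    and the posterior spread of the sum and difference combinations.
    """
    net = builtin_model("birth_death")
    c_true, x0 = net.default_params, net.x0
    obs = ObservationOperator((0,), equidistant_times(t_end, n_times))
    data = simulate_ensemble(net, c_true, x0, obs, n_replicates, seed)
    moments = compute_sample_moments(data)
    x0_scalar = float(x0[0])

    def model(c):
        m, v = birth_death_analytic(c, x0_scalar, obs.times)
        return m[:, None], v[:, None, None]

    priors = tuple(GammaPrior(prior_shape, prior_shape / ct) for ct in c_true)
    chain = mcmc_metropolis(
        lambda c: log_likelihood_mean_only(c, moments, model),
        priors, c_true.copy(), n_steps=n_steps, burn_in=burn_in,
        seed=seed + 1)
    summary = chain_summary(chain, combos={"c1+c2": [1.0, 1.0],
                                           "c1-c2": [1.0, -1.0]})
    return {
        "net": net, "moments": moments, "chain": chain, "summary": summary,
        "c_true": c_true, "priors": priors,
        "sd_sum": summary["c1+c2"]["sd"], "sd_diff": summary["c1-c2"]["sd"],
        "sd_ratio_sum_over_diff": summary["c1+c2"]["sd"] / summary["c1-c2"]["sd"],
    }
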