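"""Weighted moment-residual cost functions under partial observation.

The distance of order n between sample moments and moment-ODE predictions is

    Delta_n(c) = sum_i w_i sum_k || nu_hat_i(t_k) - nu_tilde_i(t_k; c) ||^2,

with order-1 terms comparing means of the observed components and order-2
terms comparing the observed covariance block (packed upper triangle, each
distinct entry counted once).  The residual vector stacks, time-major, the
sqrt(w_1)-scaled mean residuals followed by the sqrt(w_2)-scaled covariance
residuals, so that cost(c) == ||residuals(c)||^2 exactly.

``log_likelihood_mean_only`` is the mean-only Gaussian likelihood that scores
the per-time sample mean under Normal(m(t_k; c), v(t_k; c)/N); it deliberately
never compares the sample variance with the model variance, which is what
makes it blind along mean-preserving parameter ridges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CostEvaluationError, ValidationError
from .moment_systems import (MomentSystem, pack_indices, solve_moment_system,
                             DEFAULT_ATOL, DEFAULT_RTOL)
from .networks import ObservationOperator
from .sample_moments import SampleMomentSeries

__all__ = ["CostSpec", "predict_observed_moments", "residuals", "cost",
           "residual_length", "log_likelihood_mean_only"]


@dataclass
class CostSpec:
    """Everything needed to evaluate a moment-fitting cost at a parameter point."""

    system: MomentSystem
    obs: ObservationOperator
    data: SampleMomentSeries
    x0: np.ndarray
    order: int = 2
    weights: tuple = (1.0, 1.0)
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.order not in (1, 2):
            raise ValidationError("cost order must be 1 or 2")
        w = np.asarray(self.weights, dtype=float)
        if len(w) < self.order or np.any(w[:self.order] < 0) or not np.any(w[:self.order] > 0):
            raise ValidationError("weights must be non-negative and not all zero")
        if not np.allclose(self.data.times, self.obs.times):
            raise ValidationError("data times must equal the observation times")
        if self.data.mean.shape[1] != self.obs.d:
            raise ValidationError("data component count must match observed indices")
        if self.order >= 2 and self.data.cov is None:
            raise ValidationError("order-2 cost requires sample covariances in the data")
        if self.order >= 2 and self.system.order < 2:
            raise ValidationError("order-2 cost requires a second-order moment system")

    @property
    def net(self):
        return self.system.net


def predict_observed_moments(ms: MomentSystem, c, x0, obs: ObservationOperator,
                             rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL):
    """Solve the full moment system, then select the observed components.

    Unobserved species still shape the prediction through the coupled
    dynamics; the selection (splitting) happens only after solving.
    """
    for i in obs.observed_indices:
        if not 0 <= i < ms.net.n_species:
            raise ValidationError(f"observed index {i} out of range")
    traj = solve_moment_system(ms, c, x0, obs.times, rtol=rtol, atol=atol)
    idx = list(obs.observed_indices)
    mean = traj.mean[:, idx]
    cov = None if traj.cov is None else traj.cov[np.ix_(range(obs.K), idx, idx)]
    return mean, cov


def residual_length(spec: CostSpec):
    k, d = spec.obs.K, spec.obs.d
    n = k * d
    if spec.order >= 2:
        n += k * d * (d + 1) // 2
    return n


def residuals(c, spec: CostSpec):
    """Time-major residual vector; mean block first, then covariance block."""
    mean, cov = predict_observed_moments(spec.system, c, spec.x0, spec.obs,
                                         rtol=spec.rtol, atol=spec.atol)
    w = spec.weights
    parts = [np.sqrt(w[0]) * (spec.data.mean - mean).ravel()]
    if spec.order >= 2:
        tri = pack_indices(spec.obs.d)
        dm = spec.data.cov - cov
        parts.append(np.sqrt(w[1]) *
                     np.stack([dm[:, i, j] for i, j in tri], axis=1).ravel())
    return np.concatenate(parts)


def cost(c, spec: CostSpec):
    r = residuals(c, spec)
    return float(r @ r)


def log_likelihood_mean_only(c, data: SampleMomentSeries, model, x0=None,
                             obs: ObservationOperator = None):
    """Gaussian log-likelihood of the per-time sample means.

    ``model`` is either a :class:`MomentSystem` (then ``x0`` and ``obs`` are
    required) or a callable ``model(c) -> (mean K x d, cov K x d x d)``.  The
    sample mean at t_k is scored under Normal(m(t_k; c), V(t_k; c)/N); the
    sample covariance itself never enters.
    """
    if isinstance(model, MomentSystem):
        if x0 is None or obs is None:
            raise ValidationError("x0 and obs required with a MomentSystem model")
        mean, cov = predict_observed_moments(model, c, x0, obs)
    else:
        mean, cov = model(c)
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
    if cov is None:
        raise ValidationError("mean-only likelihood needs a model variance")
    n = data.n_replicates
    d = mean.shape[1]
    if d == 1:
        v = cov.reshape(data.K) / n
        if np.any(v <= 0):
            raise CostEvaluationError("non-positive model variance")
        r = data.mean[:, 0] - mean[:, 0]
        return float(-0.5 * np.sum(np.log(2 * np.pi * v) + r * r / v))
    ll = 0.0
    for k in range(data.K):
        vk = cov[k] / n
        if np.any(np.diag(vk) <= 0):
            raise CostEvaluationError(
                f"non-positive model variance at t={data.times[k]}")
        try:
            ll += stats.multivariate_normal.logpdf(data.mean[k], mean=mean[k],
                                                   cov=vk)
        except np.linalg.LinAlgError as exc:
            raise CostEvaluationError(str(exc)) from exc
    return float(ll)
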