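"""Hessian eigen-analysis of cost landscapes: parameter sloppiness.

Small (relative to the largest) Hessian eigenvalues at a minimizer mark
directions along which the cost is nearly flat -- parameter combinations the
data barely constrain.  The Gauss-Newton Hessian 2 J^T J (exact at a
zero-residual minimizer) and a central-second-difference Hessian are provided,
in linear parameter scale or in log scale (theta = log c), which measures
relative parameter changes and is the natural choice when parameters differ in
units or magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import CostSpec, cost as cost_fn, residuals as residuals_fn
from .errors import CostEvaluationError, ValidationError

__all__ = ["SloppinessReport", "hessian", "gauss_newton_hessian", "fd_hessian",
           "residual_jacobian_fd", "sloppiness_report", "levelset_scan",
           "line_scan"]


def residual_jacobian_fd(residual_fn, c, rel_step=1e-3):
    """Central-difference Jacobian of a residual vector function."""
    c = np.asarray(c, dtype=float)
    cols = []
    for i in range(len(c)):
        h = rel_step * max(abs(c[i]), 1e-12)
        cp, cm = c.copy(), c.copy()
        cp[i] += h
        cm[i] -= h
        try:
            cols.append((residual_fn(cp) - residual_fn(cm)) / (2 * h))
        except Exception as exc:
            raise CostEvaluationError(
                f"residual probe failed for component {i}: {exc}") from exc
    return np.stack(cols, axis=1)


def gauss_newton_hessian(residual_fn, c, scale="linear", rel_step=1e-3):
    """2 J^T J from the residual Jacobian; exact at zero-residual minimizers."""
    c = np.asarray(c, dtype=float)
    J = residual_jacobian_fd(residual_fn, c, rel_step=rel_step)
    if scale == "log":
        J = J * c[None, :]
    return 2.0 * (J.T @ J)


def fd_hessian(cost_fn_, c, scale="linear", rel_step=1e-2):
    """Central second differences of the cost, symmetric by construction."""
    c = np.asarray(c, dtype=float)
    p = len(c)

    if scale == "log":
        theta0 = np.log(c)
        f = lambda th: cost_fn_(np.exp(th))
        steps = np.full(p, rel_step)
        x0 = theta0
    else:
        f = cost_fn_
        steps = rel_step * np.maximum(np.abs(c), 1e-12)
        x0 = c
    f0 = f(x0)
    H = np.empty((p, p))
    for i in range(p):
        hi = steps[i]
        ei = np.zeros(p)
        ei[i] = hi
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / hi ** 2
        for j in range(i + 1, p):
            hj = steps[j]
            ej = np.zeros(p)
            ej[j] = hj
            H[i, j] = H[j, i] = (f(x0 + ei + ej) - f(x0 + ei - ej)
                                 - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * hi * hj)
    return H


def hessian(spec: CostSpec, c, method="gauss_newton", scale="linear",
            rel_step=None):
    """Hessian of the moment-fitting cost at ``c``."""
    if scale not in ("linear", "log"):
        raise ValidationError("scale must be 'linear' or 'log'")
    if method == "gauss_newton":
        return gauss_newton_hessian(lambda cv: residuals_fn(cv, spec), c,
                                    scale=scale,
                                    rel_step=1e-3 if rel_step is None else rel_step)
    if method == "finite_difference":
        return fd_hessian(lambda cv: cost_fn(cv, spec), c, scale=scale,
                          rel_step=1e-2 if rel_step is None else rel_step)
    raise ValidationError(f"unknown Hessian method '{method}'")


@dataclass
class SloppinessReport:
    hessian: np.ndarray
    eigenvalues: np.ndarray        # descending
    eigenvectors: np.ndarray       # unit-norm columns, matching order
    condition_number: float        # +inf if smallest eigenvalue below tolerance
    sloppy_directions: np.ndarray  # columns flagged below tolerance
    tolerance: float
    scale: str = "linear"
    method: str = "gauss_newton"
    evaluation_point: np.ndarray | None = None


def sloppiness_report(H, tolerance=1e-10, scale="linear",
                      method="gauss_newton", evaluation_point=None,
                      sym_tol=1e-8):
    """Eigen-decomposition of a (symmetric) Hessian with sloppiness classification.

    Eigenvalues below ``tolerance`` times the largest are classified as sloppy
    (non-identifiable) directions and the condition number reported as +inf.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValidationError("Hessian must be square")
    scale_h = max(np.max(np.abs(H)), 1e-300)
    if np.max(np.abs(H - H.T)) > sym_tol * scale_h:
        raise ValidationError("Hessian is not symmetric within tolerance")
    Hs = 0.5 * (H + H.T)
    w, v = np.linalg.eigh(Hs)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    lam_max = max(w[0], 0.0)
    sloppy = w < tolerance * lam_max
    cond = np.inf if (sloppy[-1] or w[-1] <= 0) else float(w[0] / w[-1])
    return SloppinessReport(
        hessian=Hs, eigenvalues=w, eigenvectors=v, condition_number=cond,
        sloppy_directions=v[:, sloppy], tolerance=tolerance, scale=scale,
        method=method,
        evaluation_point=None if evaluation_point is None
        else np.asarray(evaluation_point, dtype=float))


def line_scan(spec_or_fn, center, direction, offsets):
    """Cost along center + s * direction for each s in offsets."""
    f = spec_or_fn if callable(spec_or_fn) else (lambda cv: cost_fn(cv, spec_or_fn))
    center = np.asarray(center, dtype=float)
    direction = np.asarray(direction, dtype=float)
    vals = np.empty(len(offsets))
    for i, s in enumerate(offsets):
        c = center + s * direction
        if np.any(c <= 0):
            raise ValidationError("scan leaves the positive orthant")
        vals[i] = f(c)
    return vals


def levelset_scan(spec_or_fn, center, direction1, direction2, offsets1, offsets2):
    """Cost on a 2-D grid spanned by two directions, for contour plots."""
    f = spec_or_fn if callable(spec_or_fn) else (lambda cv: cost_fn(cv, spec_or_fn))
    center = np.asarray(center, dtype=float)
    d1 = np.asarray(direction1, dtype=float)
    d2 = np.asarray(direction2, dtype=float)
    out = np.empty((len(offsets1), len(offsets2)))
    for i, a in enumerate(offsets1):
        for j, b in enumerate(offsets2):
            c = center + a * d1 + b * d2
            if np.any(c <= 0):
                raise ValidationError("grid leaves the positive orthant")
            out[i, j] = f(c)
    return out
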