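"""Closed ODE systems for approximate moments up to order 2.

Three constructions are provided, all derived symbolically from the network's
propensity expressions and then compiled to fast numeric callables:

* ``exact_moment_system`` -- closure-free mean/covariance equations, valid
  exactly when every propensity is affine in the state:
  dm/dt = S h(m),  dV/dt = S J_h V + V J_h' S' + S diag(h(m)) S'.
* ``normal_closure_1d`` -- for one-dimensional state spaces, mean/variance
  equations from the Fokker-Planck drift A(x) = sum_j s_j h_j(x) and diffusion
  B(x) = sum_j s_j^2 h_j(x), Taylor-expanded about the mean with the third
  central moment set to zero (normal closure):
  dm/dt = A(m) + A''(m) v / 2,  dv/dt = 2 A'(m) v + B(m) + B''(m) v / 2.
* ``lna_system`` -- linear noise approximation: the mean solves the
  macroscopic rate equation dPhi/dt = S h(Phi) and the covariance the
  Lyapunov-type equation dV/dt = J V + V J' + S diag(h(Phi)) S' with
  J = S (dh/dx)(Phi).

Covariance matrices are packed row-major over the upper triangle
((0,0), (0,1), ..., (1,1), ...); all modules share this convention.
A truncated chemical-master-equation integrator is included as a brute-force
oracle for small state spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp
from scipy import sparse
from scipy.integrate import solve_ivp

from .errors import NotApplicableError, SolverError, ValidationError
from .networks import ReactionNetwork

__all__ = [
    "MomentSystem", "MomentTrajectory",
    "exact_moment_system", "normal_closure_1d", "lna_system",
    "macroscopic_system", "solve_moment_system", "macroscopic_solve",
    "birth_death_analytic", "cme_truncated_moments",
    "pack_indices", "pack_matrix", "unpack_matrix",
    "DEFAULT_RTOL", "DEFAULT_ATOL",
]

# tighter than fitting needs, so integration error never masquerades as
# model error
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def pack_indices(u):
    """Row-major upper-triangle index pairs for a u x u symmetric matrix."""
    return [(i, j) for i in range(u) for j in range(i, u)]


def pack_matrix(m):
    m = np.asarray(m)
    u = m.shape[0]
    return np.array([m[i, j] for i, j in pack_indices(u)])


def unpack_matrix(vec, u):
    out = np.empty((u, u), dtype=float)
    for (i, j), v in zip(pack_indices(u), vec):
        out[i, j] = v
        out[j, i] = v
    return out


@dataclass
class MomentSystem:
    """A closed, parameter-dependent ODE system for stacked moments."""

    kind: str
    net: ReactionNetwork
    order: int
    state_layout: list
    dim: int
    rhs: callable        # (z, c) -> dz/dt
    jac_z: callable      # (z, c) -> dim x dim
    jac_c: callable      # (z, c) -> dim x n_params

    def initial_state(self, x0, initial_cov=None):
        """Stacked initial moments for a deterministic initial state."""
        x0 = np.asarray(x0, dtype=float)
        u = self.net.n_species
        if x0.shape != (u,):
            raise ValidationError("x0 must have one entry per species")
        if self.order == 1:
            return x0.copy()
        if initial_cov is None:
            vpart = np.zeros(u * (u + 1) // 2)
        else:
            vpart = pack_matrix(np.asarray(initial_cov, dtype=float))
        return np.concatenate([x0, vpart])


@dataclass
class MomentTrajectory:
    """Moment-system solution sampled at requested times."""

    times: np.ndarray
    mean: np.ndarray               # K x u
    cov: np.ndarray | None         # K x u x u
    params: np.ndarray
    leak: np.ndarray | None = None  # truncated-CME diagnostic only


def _sym_state(net, order):
    u = net.n_species
    m = sp.Matrix(sp.symbols([f"__m_{s}" for s in net.species_names]))
    if order == 1:
        return m, None, list(m)
    vsyms = {}
    for i, j in pack_indices(u):
        vsyms[(i, j)] = sp.Symbol(f"__v_{i}_{j}")
    V = sp.Matrix(u, u, lambda i, j: vsyms[(min(i, j), max(i, j))])
    z = list(m) + [vsyms[ij] for ij in pack_indices(u)]
    return m, V, z


def _compile(net, kind, order, exprs, z):
    F = sp.Matrix(exprs)
    zsyms = sp.Matrix(z)
    csyms = sp.Matrix(net.c_syms)
    f = sp.lambdify((z, net.c_syms), list(F), "numpy")
    jz = sp.lambdify((z, net.c_syms), F.jacobian(zsyms), "numpy")
    jc = sp.lambdify((z, net.c_syms), F.jacobian(csyms), "numpy")

    def rhs(zv, cv):
        return np.asarray(f(tuple(zv), tuple(cv)), dtype=float)

    def jac_z(zv, cv):
        return np.asarray(jz(tuple(zv), tuple(cv)), dtype=float)

    def jac_c(zv, cv):
        return np.asarray(jc(tuple(zv), tuple(cv)), dtype=float)

    u = net.n_species
    layout = [f"m[{s}]" for s in net.species_names]
    if order >= 2:
        layout += [f"V[{net.species_names[i]},{net.species_names[j]}]"
                   for i, j in pack_indices(u)]
    return MomentSystem(kind, net, order, layout, len(z), rhs, jac_z, jac_c)


def _cached(net, key, builder):
    cache = net._cache
    if key not in cache:
        cache[key] = builder()
    return cache[key]


def _h_and_jac(net, at):
    """Propensity vector and its state-Jacobian, substituted at a mean vector."""
    subs = dict(zip(net.x_syms, list(at)))
    h = sp.Matrix([e.subs(subs) for e in net.propensity_exprs])
    Jh = sp.Matrix(net.n_reactions, net.n_species,
                   lambda j, i: sp.diff(net.propensity_exprs[j], net.x_syms[i]).subs(subs))
    return h, Jh


def exact_moment_system(net: ReactionNetwork) -> MomentSystem:
    """Closure-free mean/covariance ODEs; requires affine propensities."""
    def build():
        for j, kind in enumerate(net.propensity_kind):
            if kind != "affine":
                raise NotApplicableError(
                    f"exact moment equations require affine propensities; "
                    f"reaction {net.reaction_names[j]} is {kind}")
        m, V, z = _sym_state(net, 2)
        S = sp.Matrix(net.stoich.tolist())
        h, Jh = _h_and_jac(net, m)
        mean_rhs = S * h
        A = S * Jh
        cov_rhs = A * V + V * A.T + S * sp.diag(*h) * S.T
        exprs = list(mean_rhs) + [cov_rhs[i, j] for i, j in pack_indices(net.n_species)]
        return _compile(net, "exact_affine", 2, exprs, z)
    return _cached(net, "exact_affine", build)


def normal_closure_1d(net: ReactionNetwork) -> MomentSystem:
    """Normal (third-central-moment-zero) closure for 1-D state spaces."""
    def build():
        if net.n_species != 1:
            raise NotApplicableError(
                "normal closure implemented for one-dimensional state spaces only")
        m, V, z = _sym_state(net, 2)
        x = net.x_syms[0]
        mm, vv = m[0], V[0, 0]
        A = sum(int(net.stoich[0, j]) * net.propensity_exprs[j]
                for j in range(net.n_reactions))
        B = sum(int(net.stoich[0, j]) ** 2 * net.propensity_exprs[j]
                for j in range(net.n_reactions))
        A, B = sp.sympify(A), sp.sympify(B)
        Am = A.subs(x, mm)
        dm = Am + sp.diff(A, x, 2).subs(x, mm) * vv / 2
        dv = (2 * sp.diff(A, x).subs(x, mm) * vv + B.subs(x, mm)
              + sp.diff(B, x, 2).subs(x, mm) * vv / 2)
        return _compile(net, "normal_closure_1d", 2, [dm, dv], z)
    return _cached(net, "normal_closure_1d", build)


def lna_system(net: ReactionNetwork) -> MomentSystem:
    """Linear noise approximation: macroscopic mean + Lyapunov covariance."""
    def build():
        m, V, z = _sym_state(net, 2)
        S = sp.Matrix(net.stoich.tolist())
        h, Jh = _h_and_jac(net, m)
        mean_rhs = S * h
        J = S * Jh
        cov_rhs = J * V + V * J.T + S * sp.diag(*h) * S.T
        exprs = list(mean_rhs) + [cov_rhs[i, j] for i, j in pack_indices(net.n_species)]
        return _compile(net, "lna", 2, exprs, z)
    return _cached(net, "lna", build)


def macroscopic_system(net: ReactionNetwork) -> MomentSystem:
    """Deterministic rate equation dx/dt = S h(x, c) (mean only)."""
    def build():
        m, _, z = _sym_state(net, 1)
        S = sp.Matrix(net.stoich.tolist())
        h, _ = _h_and_jac(net, m)
        return _compile(net, "macroscopic", 1, list(S * h), z)
    return _cached(net, "macroscopic", build)


def solve_moment_system(ms: MomentSystem, c, x0, times,
                        rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                        method="LSODA", initial_cov=None) -> MomentTrajectory:
    """Integrate a moment system and resample at the requested times."""
    c = np.asarray(c, dtype=float)
    if c.shape != (ms.net.n_params,) or np.any(c < 0):
        raise ValidationError("parameter vector must be non-negative, one entry per parameter")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be non-negative and strictly increasing")
    z0 = ms.initial_state(x0, initial_cov=initial_cov)
    u = ms.net.n_species
    if times[-1] == 0.0:
        zs = z0[None, :]
    else:
        sol = solve_ivp(lambda t, zv: ms.rhs(zv, c), (0.0, times[-1]), z0,
                        method=method, rtol=rtol, atol=atol, t_eval=times,
                        jac=lambda t, zv: ms.jac_z(zv, c))
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise SolverError(f"moment ODE integration failed: {sol.message}", params=c)
        zs = sol.y.T
        if times[0] == 0.0:
            zs[0] = z0
    mean = zs[:, :u]
    cov = None
    if ms.order >= 2:
        cov = np.stack([unpack_matrix(row[u:], u) for row in zs])
    return MomentTrajectory(times, mean, cov, c)


def macroscopic_solve(net, c, x0, times, **kw):
    """Solve the macroscopic rate equation; mean-only trajectory."""
    return solve_moment_system(macroscopic_system(net), c, x0, times, **kw)


def birth_death_analytic(c, x0, times):
    """Closed-form mean/variance of the linear birth-death process.

    m(t) = x0 exp(d t) with d = c1 - c2, and
    v(t) = x0 (c1 + c2)/d exp(d t)(exp(d t) - 1), with the continuous limit
    v(t) = 2 c1 x0 t when c1 = c2.
    """
    c1, c2 = float(c[0]), float(c[1])
    x0 = float(np.asarray(x0).reshape(-1)[0])
    t = np.asarray(times, dtype=float)
    d = c1 - c2
    s = c1 + c2
    mean = x0 * np.exp(d * t)
    if d == 0.0:
        var = 2.0 * c1 * x0 * t
    else:
        var = x0 * s * np.exp(d * t) * np.expm1(d * t) / d
    return mean, var


def cme_truncated_moments(net: ReactionNetwork, c, x0, times, state_cap,
                          max_states=200_000, rtol=1e-8, atol=1e-12):
    """Brute-force oracle: integrate the truncated chemical master equation.

    Each species is capped at ``state_cap`` (scalar or per-species); the
    probability vector ODE p' = A p is integrated on the resulting lattice and
    exact mean/covariance of the (renormalized) truncated distribution are
    reported.  Probability mass leaving the box is lost from the generator and
    reported per time in ``leak``.
    """
    c = np.asarray(c, dtype=float)
    caps = np.broadcast_to(np.asarray(state_cap, dtype=int), (net.n_species,)).copy()
    dims = caps + 1
    n_states = int(np.prod(dims))
    if n_states > max_states:
        raise ValidationError(
            f"truncated state space has {n_states} states (> {max_states})")
    x0 = np.asarray(x0, dtype=int)
    if np.any(x0 > caps):
        raise ValidationError("x0 outside the truncation box")
    grids = np.indices(dims).reshape(net.n_species, -1)   # u x n_states
    states = grids.T
    rows, cols_idx, vals = [], [], []
    diag = np.zeros(n_states)
    for j in range(net.n_reactions):
        rates = np.asarray(net._h_numpy(tuple(grids.astype(float)), tuple(c)),
                           dtype=object)
        rate_j = np.broadcast_to(np.asarray(rates[j], dtype=float), (n_states,))
        rate_j = np.maximum(rate_j, 0.0)
        target = states + net.stoich[:, j][None, :]
        inside = np.all((target >= 0) & (target <= caps[None, :]), axis=1)
        src = np.arange(n_states)
        tgt_idx = np.ravel_multi_index(target[inside].T, dims)
        rows.append(tgt_idx)
        cols_idx.append(src[inside])
        vals.append(rate_j[inside])
        diag -= rate_j
    rows.append(np.arange(n_states))
    cols_idx.append(np.arange(n_states))
    vals.append(diag)
    A = sparse.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols_idx))),
                          shape=(n_states, n_states))
    p0 = np.zeros(n_states)
    p0[np.ravel_multi_index(x0, dims)] = 1.0
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(lambda t, p: A @ p, (0.0, times[-1]), p0, method="BDF",
                    jac=A, rtol=rtol, atol=atol, t_eval=times)
    if not sol.success:
        raise SolverError(f"CME integration failed: {sol.message}", params=c)
    ps = np.maximum(sol.y.T, 0.0)
    if times[0] == 0.0:
        ps[0] = p0
    u = net.n_species
    mean = np.empty((len(times), u))
    cov = np.empty((len(times), u, u))
    leak = np.empty(len(times))
    xs = states.astype(float)
    for k, p in enumerate(ps):
        mass = p.sum()
        leak[k] = 1.0 - mass
        q = p / mass
        mu = q @ xs
        centered = xs - mu[None, :]
        mean[k] = mu
        cov[k] = (centered * q[:, None]).T @ centered
    return MomentTrajectory(times, mean, cov, c, leak=leak)
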