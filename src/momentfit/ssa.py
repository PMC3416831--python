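"""Exact stochastic simulation (Gillespie direct method) and ensemble data.

The direct method draws exponential waiting times with rate equal to the total
propensity and picks the firing reaction with probability proportional to its
propensity.  A simulation halts at ``t_max`` or when the total propensity
reaches zero (absorbing state); later observation times then report the
absorbing state.  Sampling at an observation time uses the right-continuous
convention: the state *after* the last jump at or before that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .networks import ObservationOperator, ReactionNetwork

__all__ = ["Trajectory", "DataTensor", "simulate_ssa", "sample_at_times",
           "simulate_ensemble"]


@dataclass
class Trajectory:
    """One realization of the jump process (piecewise constant, cadlag)."""

    jump_times: np.ndarray      # includes t=0 as first entry
    states: np.ndarray          # one row per jump time
    reaction_ids: np.ndarray    # fired reaction per jump (internal only)
    t_end: float


@dataclass
class DataTensor:
    """Replicate x time x observed-species counts (the data of Eq.-style protocols)."""

    values: np.ndarray
    times: np.ndarray
    observed_indices: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.times = np.asarray(self.times, dtype=float)
        self.observed_indices = tuple(int(i) for i in self.observed_indices)
        if self.values.ndim != 3:
            raise ValidationError("values must be N x K x d")
        n, k, d = self.values.shape
        if n < 1 or k != len(self.times) or d != len(self.observed_indices):
            raise ValidationError("DataTensor shape inconsistent with times / observed indices")

    @property
    def n_replicates(self):
        return self.values.shape[0]


def _rng_of(rng):
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_ssa(net: ReactionNetwork, c, x0, t_max, rng):
    """Exact direct-method realization on [0, t_max]."""
    if t_max <= 0:
        raise ValidationError("t_max must be positive")
    rng = _rng_of(rng)
    x0 = np.asarray(x0, dtype=int)
    if x0.shape != (net.n_species,) or np.any(x0 < 0):
        raise ValidationError("x0 must be a non-negative integer state")
    h = net.propensity_fn(c)
    cols = [tuple(int(v) for v in net.stoich[:, j]) for j in range(net.n_reactions)]
    x = [int(v) for v in x0]
    t = 0.0
    times = [0.0]
    states = [tuple(x)]
    fired = []
    expo = rng.exponential
    unif = rng.random
    while True:
        a = h(*x)
        a0 = 0.0
        for v in a:
            a0 += v
        if a0 <= 0.0:
            break
        t_next = t + expo() / a0
        if t_next > t_max:
            break
        r = unif() * a0
        j = 0
        acc = a[0]
        while acc < r:
            j += 1
            acc += a[j]
        col = cols[j]
        x = [xi + si for xi, si in zip(x, col)]
        t = t_next
        times.append(t)
        states.append(tuple(x))
        fired.append(j)
    return Trajectory(np.asarray(times), np.asarray(states, dtype=int),
                      np.asarray(fired, dtype=int), float(t_max))


def sample_at_times(traj: Trajectory, times):
    """Right-continuous evaluation of a trajectory at given times (K x u)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(times > traj.t_end):
        raise ValidationError("query times must lie within [0, t_max]")
    idx = np.searchsorted(traj.jump_times, times, side="right") - 1
    return traj.states[idx]


def _simulate_observed(h, cols, x0, times, rng):
    """States at the sorted observation times without storing the full path."""
    x = list(x0)
    k = len(times)
    out = np.empty((k, len(x0)), dtype=int)
    t = 0.0
    ti = 0
    expo = rng.exponential
    unif = rng.random
    t_last = times[-1]
    while ti < k:
        a = h(*x)
        a0 = 0.0
        for v in a:
            a0 += v
        if a0 <= 0.0:
            while ti < k:
                out[ti] = x
                ti += 1
            break
        t_next = t + expo() / a0
        while ti < k and times[ti] < t_next:
            out[ti] = x
            ti += 1
        if t_next > t_last:
            break
        r = unif() * a0
        j = 0
        acc = a[0]
        while acc < r:
            j += 1
            acc += a[j]
        col = cols[j]
        x = [xi + si for xi, si in zip(x, col)]
        t = t_next
    return out


def simulate_ensemble(net: ReactionNetwork, c, x0, obs: ObservationOperator,
                      n_replicates, seed):
    """N independent realizations reduced to observed components at obs.times.

    Each replicate runs on its own deterministic substream spawned from the
    master seed, so any replicate is reproducible in isolation and parallel or
    serial execution order does not matter.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    x0 = np.asarray(x0, dtype=int)
    if x0.shape != (net.n_species,) or np.any(x0 < 0):
        raise ValidationError("x0 must be a non-negative integer state")
    for i in obs.observed_indices:
        if not 0 <= i < net.n_species:
            raise ValidationError(f"observed index {i} out of range")
    h = net.propensity_fn(c)
    cols = [tuple(int(v) for v in net.stoich[:, j]) for j in range(net.n_reactions)]
    obs_idx = list(obs.observed_indices)
    x0_list = [int(v) for v in x0]
    values = np.empty((n_replicates, obs.K, obs.d), dtype=int)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    times = obs.times
    for i, child in enumerate(children):
        full = _simulate_observed(h, cols, x0_list, times, np.random.default_rng(child))
        values[i] = full[:, obs_idx]
    meta = {"seed": int(seed) if np.isscalar(seed) else None,
            "model": net.name, "params": [float(v) for v in np.asarray(c, float)],
            "x0": [int(v) for v in x0]}
    return DataTensor(values, times, obs.observed_indices, meta)
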