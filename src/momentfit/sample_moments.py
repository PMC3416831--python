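"""Per-time sample moments of the observed components of an ensemble.

The sample mean at time t_k averages the observed state over replicates; the
sample covariance is the unbiased (divisor N-1) estimator by default, with a
``ddof=0`` switch for the divisor-N convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientReplicatesError, ValidationError
from .ssa import DataTensor

__all__ = ["SampleMomentSeries", "compute_sample_moments"]


@dataclass
class SampleMomentSeries:
    """Sample mean (K x d) and covariance (K x d x d) series."""

    times: np.ndarray
    order: int
    mean: np.ndarray
    cov: np.ndarray | None
    n_replicates: int
    observed_indices: tuple = ()

    @property
    def K(self):
        return len(self.times)

    @property
    def d(self):
        return self.mean.shape[1]


def compute_sample_moments(data: DataTensor, order=2, ddof=1):
    """Compute mean (and, for order 2, covariance) per observation time."""
    if order not in (1, 2):
        raise ValidationError("moment order must be 1 or 2")
    n, k, d = data.values.shape
    values = data.values.astype(float)
    mean = values.mean(axis=0)
    cov = None
    if order >= 2:
        if n < 2:
            raise InsufficientReplicatesError(
                "sample covariance requires at least 2 replicates")
        if n <= d:
            raise InsufficientReplicatesError(
                f"N={n} replicates for d={d} observed components: the plain "
                "empirical covariance is rank-deficient; increase N")
        centered = values - mean[None, :, :]
        cov = np.einsum("nki,nkj->kij", centered, centered) / (n - ddof)
    return SampleMomentSeries(np.asarray(data.times, float), order, mean, cov,
                              n, data.observed_indices)
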