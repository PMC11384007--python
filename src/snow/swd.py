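"""Sliced squared Wasserstein-2 distance between sample sets.

The latent-space regularizers all measure how far a set of points is from a
reference distribution (the standard normal).  The sliced estimator projects
both sample sets onto random unit directions, sorts each 1-D projection, and
averages the squared differences of the order statistics:

    SW2(X, Y) = 1 / (n_proj * n) * sum_w || sort(w'X) - sort(w'Y) ||^2

This is the *squared* distance (no square root), exact for the empirical 1-D
W2^2 on each slice.  Functions accept either plain ndarrays or autodiff
Tensors; in the latter case gradients flow through the sorting permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ProjectionSet",
    "sample_unit_directions",
    "sliced_w2",
    "sliced_w2_to_std_normal",
]


@dataclass(frozen=True)
class ProjectionSet:
    """Random projection directions: rows are unit vectors in R^d."""

    directions: np.ndarray  # (n_proj, d)

    def __post_init__(self):
        d = np.atleast_2d(self.directions)
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("projection directions must have unit norm")

    @property
    def n_proj(self) -> int:
        return self.directions.shape[0]

    @property
    def dim(self) -> int:
        return self.directions.shape[1]


def sample_unit_directions(
    d: int, n_proj: int = 50, seed: int | np.random.Generator = 0
) -> ProjectionSet:
    """i.i.d. uniform unit vectors on the sphere (normalized Gaussians)."""
    if d < 1 or n_proj < 1:
        raise ValueError("d and n_proj must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_proj, d))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return ProjectionSet(v)


def _project_sorted(X, directions: np.ndarray):
    """Project samples onto each direction and sort within each slice."""
    if isinstance(X, Tensor):
        return ad.sort_ascending(X @ Tensor(directions.T), axis=0)
    return np.sort(np.asarray(X, float) @ directions.T, axis=0)


def sliced_w2(X, Y, projections: ProjectionSet, rng: np.random.Generator | None = None):
    """Sliced squared W2 between two sample sets of equal dimension.

    When the sample counts differ, the larger set is subsampled uniformly
    without replacement to match (the order-statistics pairing requires equal
    n).  Returns a float for ndarray inputs, a scalar Tensor when either input
    is a Tensor.
    """
    nx = X.shape[0]
    ny = Y.shape[0]
    if nx == 0 or ny == 0:
        raise ValueError("empty sample set")
    if nx != ny:
        rng = rng if rng is not None else np.random.default_rng(0)
        if nx > ny:
            X = X[np.sort(rng.choice(nx, ny, replace=False))]
        else:
            Y = Y[np.sort(rng.choice(ny, nx, replace=False))]
    n = min(nx, ny)
    Px = _project_sorted(X, projections.directions)
    Py = _project_sorted(Y, projections.directions)
    diff = Px - Py
    total = (diff * diff).sum() if isinstance(diff, Tensor) else float(np.sum(diff * diff))
    return total * (1.0 / (projections.n_proj * n))


@lru_cache(maxsize=64)
def _normal_quantiles(n: int) -> np.ndarray:
    """Midpoint standard-normal quantiles Phi^-1((i - 1/2) / n)."""
    from scipy.special import ndtri

    return ndtri((np.arange(1, n + 1) - 0.5) / n)


def sliced_w2_to_std_normal(
    Z,
    projections: ProjectionSet,
    rng: np.random.Generator | None = None,
    reference: str = "quantile",
):
    """Sliced squared W2 between samples ``Z`` and the standard normal.

    ``reference`` selects the per-slice comparison set.  Any unit projection
    of N(0, I) is a standard normal, so the reference can be either a fresh
    Gaussian draw of matching size (``"sample"``, stochastic per call) or the
    deterministic midpoint quantiles of N(0, 1) (``"quantile"``).  The
    quantile reference is used during training: it removes the reference's
    sampling noise from the gradient, which otherwise dominates the small
    per-timepoint terms.
    """
    n, d = Z.shape
    if reference == "sample":
        rng = rng if rng is not None else np.random.default_rng(0)
        Y = rng.standard_normal((n, d))
        return sliced_w2(Z, Y, projections, rng=rng)
    if reference != "quantile":
        raise ValueError("reference must be 'sample' or 'quantile'")
    if n < 1:
        raise ValueError("empty sample set")
    Pz = _project_sorted(Z, projections.directions)
    q = _normal_quantiles(n)[:, None]
    diff = Pz - q
    total = (diff * diff).sum() if isinstance(diff, Tensor) else float(np.sum(diff * diff))
    return total * (1.0 / (projections.n_proj * n))
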