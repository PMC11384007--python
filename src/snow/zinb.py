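"""Zero-inflated negative binomial (ZINB) probability machinery.

The observation model for a count ``y`` of one gene in one cell is a negative
binomial with mean ``mu = rho * l`` (count fraction times library size) and
inverse dispersion ``theta``, mixed with a dropout gate ``h`` (the probability
that the observation is *not* dropped out):

    P(y = 0)  = (1 - h) + h * (theta / (theta + mu))**theta
    P(y > 0)  = h * NB(y; mu, theta)

Equivalently as a generative process: w ~ Gamma(shape=theta, scale=rho/theta)
(so E[w] = rho), y ~ Poisson(l * w), and the result is masked to zero with
probability 1 - h.  Everything is computed in log space via log-gamma for
stability; the zero branch uses log-sum-exp.

Two parallel implementations are provided: plain numpy (inference and
diagnostics) and graph-building on :class:`~snow.autodiff.Tensor` (training).
Tests tie the two together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ZINBParams",
    "nb_log_pmf",
    "zinb_log_pmf",
    "cell_log_likelihood",
    "zinb_log_pmf_t",
    "sample_counts",
    "sample_cell",
]


@dataclass
class ZINBParams:
    """Per-cell-per-gene ZINB parameters (C x G arrays).

    rho: count fractions, each cell's row sums to 1;
    theta: inverse dispersions, strictly positive;
    h: dropout gates, clamped inside (0, 1) by the decoder (default
    [0.01, 0.99]).
    """

    rho: np.ndarray
    theta: np.ndarray
    h: np.ndarray
    h_clamp: tuple = (0.01, 0.99)

    def __post_init__(self):
        self.rho = np.atleast_2d(np.asarray(self.rho, float))
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        self.h = np.atleast_2d(np.asarray(self.h, float))
        if not (self.rho.shape == self.theta.shape == self.h.shape):
            raise ValueError("rho, theta, h must share shape")
        sums = self.rho.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("per-cell rho must sum to 1 within 1e-6")
        if np.any(self.theta <= 0):
            raise ValueError("theta must be strictly positive")
        lo, hi = self.h_clamp
        if np.any(self.h < lo - 1e-12) or np.any(self.h > hi + 1e-12):
            raise ValueError(f"h must lie within the clamp bounds [{lo}, {hi}]")

    def row(self, c: int) -> "ZINBParams":
        return ZINBParams(self.rho[c : c + 1], self.theta[c : c + 1], self.h[c : c + 1],
                          self.h_clamp)


def _check_domain(mean, theta):
    mean = np.asarray(mean, float)
    theta = np.asarray(theta, float)
    if np.any(~np.isfinite(mean)) or np.any(mean <= 0):
        raise ValueError("NB mean must be finite and > 0")
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0):
        raise ValueError("theta must be finite and > 0")
    return mean, theta


def nb_log_pmf(y, mean, theta) -> np.ndarray:
    """Negative binomial log pmf with mean ``mean`` and inverse dispersion
    ``theta`` (variance = mean + mean^2 / theta)."""
    mean, theta = _check_domain(mean, theta)
    y = np.asarray(y, float)
    return (
        special.gammaln(y + theta)
        - special.gammaln(y + 1.0)
        - special.gammaln(theta)
        + theta * (np.log(theta) - np.log(theta + mean))
        + y * (np.log(mean) - np.log(theta + mean))
    )


def zinb_log_pmf(y, mean, theta, h) -> np.ndarray:
    """ZINB log pmf; ``h`` is the probability of *not* dropping out."""
    mean, theta = _check_domain(mean, theta)
    y = np.asarray(y, float)
    h = np.asarray(h, float)
    if np.any((h <= 0) | (h > 1)):
        raise ValueError("h must lie in (0, 1]")
    log_nb = nb_log_pmf(y, mean, theta)
    log_nb0 = theta * (np.log(theta) - np.log(theta + mean))
    with np.errstate(divide="ignore"):  # log(0) -> -inf is the h=1 edge
        log_zero = np.logaddexp(np.log1p(-h), np.log(h) + log_nb0)
    out = np.where(y == 0, log_zero, np.log(h) + log_nb)
    return out


def cell_log_likelihood(x_c, params: ZINBParams, l_c) -> tuple[float, np.ndarray]:
    """Log-likelihood of one cell's count vector.

    Returns the scalar total and the per-gene vector (the gene-wise values are
    the raw material for likelihood-over-time batch diagnostics).
    """
    x_c = np.asarray(x_c, float).ravel()
    rho = params.rho.ravel()
    theta = params.theta.ravel()
    h = params.h.ravel()
    if not (x_c.shape == rho.shape == theta.shape == h.shape):
        raise ValueError("count vector and parameter rows must share length")
    per_gene = zinb_log_pmf(x_c, rho * float(l_c), theta, h)
    return float(per_gene.sum()), per_gene


# -- graph-building (training) path ------------------------------------------

def zinb_log_pmf_t(y: np.ndarray, mean: Tensor, theta: Tensor, h: Tensor) -> Tensor:
    """Differentiable ZINB log pmf over a batch (counts are constants).

    Implemented as a single fused graph node with analytic gradients: the
    expression touches large (cells x genes) arrays ~20 times, and composing
    it from elementwise primitives dominates the training step otherwise.
    The tests pin this fused form against the plain numpy reference and
    finite differences.
    """
    y = np.asarray(y, float)
    mu_d, th_d, h_d = mean.data, theta.data, h.data
    zero = y == 0
    log_ratio0 = th_d * (np.log(th_d) - np.log(th_d + mu_d))
    log_nb = (
        special.gammaln(y + th_d)
        - special.gammaln(th_d)
        - special.gammaln(y + 1.0)
        + log_ratio0
        + y * (np.log(mu_d) - np.log(th_d + mu_d))
    )
    with np.errstate(divide="ignore"):
        log_zero = np.logaddexp(np.log1p(-h_d), np.log(h_d) + log_ratio0)
    out_data = np.where(zero, log_zero, np.log(h_d) + log_nb)

    out = ad._node(out_data, mean, theta, h)
    if out.requires_grad:
        # w: posterior weight of the "true zero" branch at y = 0
        w = np.where(zero, np.exp(np.log(h_d) + log_ratio0 - log_zero), 1.0)
        frac = th_d / (th_d + mu_d)
        def bw(g):
            if mean.requires_grad:
                d_pos = y / mu_d - (th_d + y) / (th_d + mu_d)
                d_zero = -w * th_d / (th_d + mu_d)
                mean._accum(g * np.where(zero, d_zero, d_pos))
            if theta.requires_grad:
                base = np.log(frac) + 1.0 - frac
                d_pos = special.digamma(y + th_d) - special.digamma(th_d) + base - y / (th_d + mu_d)
                d_zero = w * base
                theta._accum(g * np.where(zero, d_zero, d_pos))
            if h.requires_grad:
                d_pos = 1.0 / h_d
                d_zero = (w - (1.0 - w) * h_d / (1.0 - h_d)) / h_d
                h._accum(g * np.where(zero, d_zero, d_pos))
        out._backward = bw
    return out


# -- generative sampling ------------------------------------------------------

def sample_counts(
    rho: np.ndarray,
    theta: np.ndarray,
    h: np.ndarray,
    l,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ZINB counts via the Gamma-Poisson-Bernoulli construction."""
    rho = np.asarray(rho, float)
    theta = np.asarray(theta, float)
    h = np.asarray(h, float)
    l = np.asarray(l, float)
    if np.any(l <= 0):
        raise ValueError("library size must be positive")
    w = rng.gamma(shape=theta, scale=rho / theta)
    y = rng.poisson(np.expand_dims(l, -1) * w if rho.ndim > 1 else l * w)
    keep = rng.random(size=y.shape) < h
    return np.where(keep, y, 0)


def sample_cell(z, t_norm: float, l: float, model, rng: np.random.Generator) -> np.ndarray:
    """Generate one virtual cell from latent state ``z`` at normalized time
    ``t_norm`` with library size ``l`` using the model's decoders."""
    if l <= 0:
        raise ValueError("library size must be positive")
    z = np.atleast_2d(np.asarray(z, float))
    rho = model.decode_rho(z, t_norm)
    theta = model.decode_theta(z, t_norm)
    h = model.decode_h(z, t_norm)
    return sample_counts(rho[0], theta[0], h[0], float(l), rng)
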