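"""Priors on dietary proportions and residual scales.

The natural prior on a proportion vector constrained to the simplex is the
Dirichlet.  The default is the flat Dirichlet (every alpha = 1), which gives
each of K sources prior mean 1/K and prior variance (K-1)/(K^2 (K+1)).  An
informative prior is elicited from a target mean vector plus a single
standard deviation for the first proportion, inverted through the Dirichlet
moment formulas:

    alpha_0 = sum_k alpha_k
    E[p_k]      = alpha_k / alpha_0
    Var[p_k]    = alpha_k (alpha_0 - alpha_k) / (alpha_0^2 (alpha_0 + 1))
    Cov[p_k,p_l] = -alpha_k alpha_l / (alpha_0^2 (alpha_0 + 1))   (k != l)

The Dirichlet cannot encode separate uncertainties per source: one SD pins
down alpha_0 and the means pin down the rest.

The residual scales get a bounded-uniform prior, sigma_j ~ U(0, upper); the
default bound of 20 permil is far above realistic residual spread in
delta-value data, so the data dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DirichletPrior",
    "SigmaPrior",
    "InfeasibleVarianceError",
    "default_alpha",
    "dirichlet_moments",
    "elicit_alpha",
    "log_prior",
    "sample_prior",
]

from .model import ProportionVector


class InfeasibleVarianceError(ValueError):
    """Requested prior SD exceeds what any Dirichlet can produce."""


@dataclass(frozen=True)
class DirichletPrior:
    alpha: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.alpha, dtype=float).ravel()
        if arr.size < 2:
            raise ValueError("need at least two components")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("all alpha values must be positive and finite")
        object.__setattr__(self, "alpha", arr)

    @property
    def k(self) -> int:
        return self.alpha.size


@dataclass(frozen=True)
class SigmaPrior:
    """Uniform prior on (0, upper) for each residual SD, in permil."""

    upper: float = 20.0

    def __post_init__(self):
        if not np.isfinite(self.upper) or self.upper <= 0:
            raise ValueError("upper bound must be positive and finite")


def default_alpha(K: int) -> DirichletPrior:
    """The vague default: alpha = (1, ..., 1), uniform over the simplex."""
    if K < 2:
        raise ValueError("need at least two sources")
    return DirichletPrior(np.ones(K))


def dirichlet_moments(
    prior: DirichletPrior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean vector, variance vector and covariance matrix of the prior.

    The covariance matrix rows sum to zero — the closure constraint
    sum p_k = 1 forces every component to covary negatively with the rest.
    """
    a = prior.alpha
    a0 = a.sum()
    mean = a / a0
    denom = a0 ** 2 * (a0 + 1.0)
    cov = -np.outer(a, a) / denom
    var = a * (a0 - a) / denom
    np.fill_diagonal(cov, var)
    return mean, var, cov


def elicit_alpha(target_means, sd_first: float) -> DirichletPrior:
    """Build a Dirichlet from prior means plus one SD (on the first source).

    Moment-matching inversion: ``alpha_0 = m_1 (1 - m_1) / sd^2 - 1`` and
    ``alpha_k = m_k alpha_0``.  Infeasible when ``sd^2 >= m_1 (1 - m_1)``
    (no Dirichlet is that dispersed), which would drive ``alpha_0 <= 0``.
    """
    m = np.asarray(target_means, dtype=float).ravel()
    if m.size < 2:
        raise ValueError("need at least two prior means")
    if np.any(m <= 0) or abs(m.sum() - 1.0) > 1e-9:
        raise ValueError("prior means must be positive and sum to 1")
    if sd_first <= 0:
        raise ValueError("sd_first must be positive")
    m1 = m[0]
    if sd_first ** 2 >= m1 * (1.0 - m1):
        raise InfeasibleVarianceError(
            f"sd {sd_first} infeasible: requires sd^2 < m_1(1-m_1) = "
            f"{m1 * (1 - m1):.6g}"
        )
    a0 = m1 * (1.0 - m1) / sd_first ** 2 - 1.0
    return DirichletPrior(m * a0)


def log_prior(p: ProportionVector, prior: DirichletPrior) -> float:
    """Dirichlet log-density at p.

    Boundary points (some p_k = 0) with alpha_k < 1 have divergent density;
    by convention -inf is returned there (alpha_k > 1 boundary density is 0,
    also -inf on the log scale; alpha_k = 1 contributes nothing).
    """
    if p.k != prior.k:
        raise ValueError("dimension mismatch between p and prior")
    a = prior.alpha
    x = p.p
    norm = gammaln(a.sum()) - gammaln(a).sum()
    on_boundary = x == 0.0
    if np.any(on_boundary):
        if np.all(a[on_boundary] == 1.0):
            return float(norm + ((a - 1.0) * np.log(np.where(on_boundary, 1.0, x))).sum())
        return -np.inf
    return float(norm + ((a - 1.0) * np.log(x)).sum())


def sample_prior(prior: DirichletPrior, seed) -> ProportionVector:
    """One draw from the prior; `seed` is an int or numpy Generator."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return ProportionVector(rng.dirichlet(prior.alpha))
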