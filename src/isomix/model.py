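"""Core statistical model for stable-isotope mixing.

A consumer's isotope value on isotope ``j`` is modelled as a
proportion-weighted blend of ``K`` dietary sources.  Each source ``k``
contributes a normally distributed isotope value ``s_jk ~ N(mu_jk, omega_jk^2)``
shifted by an uncertain trophic enrichment factor (TEF)
``c_jk ~ N(lambda_jk, tau_jk^2)``, optionally weighted by the elemental
concentration ``q_jk`` of the element in that source.  Marginalizing the
source and TEF uncertainty gives, for a fixed proportion vector ``p``, a
normal observation model per isotope:

    mean_j = sum_k p_k q_jk (mu_jk + lambda_jk) / sum_k p_k q_jk
    var_j  = sum_k p_k^2 q_jk^2 (omega_jk^2 + tau_jk^2) / (sum_k p_k q_jk)^2
             + sigma_j^2

where ``sigma_j`` is a residual scale absorbing inter-consumer variation not
explained by source or TEF spread.  With equal concentrations the ratio
weights reduce to the plain proportion-weighted sums.  Isotopes are treated
as conditionally independent given the parameters (diagonal covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "MixtureObservations",
    "SourceTable",
    "TEFTable",
    "ConcentrationTable",
    "ProportionVector",
    "ResidualScale",
    "DegenerateLikelihoodError",
    "mixture_moments",
    "log_likelihood",
    "mixing_polygon_check",
]

_SIMPLEX_TOL = 1e-12


class DegenerateLikelihoodError(ValueError):
    """Raised when the total variance is zero but data are off the mean."""


def _as_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class MixtureObservations:
    """N consumers measured on J isotopes (delta-values, permil)."""

    values: np.ndarray
    isotope_names: tuple[str, ...] = ()
    consumer_ids: tuple[str, ...] = ()

    def __post_init__(self):
        arr = _as_matrix(self.values, "consumer values")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("need at least one consumer and one isotope")
        object.__setattr__(self, "values", arr)
        iso = tuple(self.isotope_names) or tuple(
            f"iso{j + 1}" for j in range(arr.shape[1])
        )
        ids = tuple(self.consumer_ids) or tuple(
            str(i + 1) for i in range(arr.shape[0])
        )
        if len(iso) != arr.shape[1]:
            raise ValueError("isotope_names length does not match columns")
        if len(ids) != arr.shape[0]:
            raise ValueError("consumer_ids length does not match rows")
        object.__setattr__(self, "isotope_names", iso)
        object.__setattr__(self, "consumer_ids", ids)

    @property
    def n_consumers(self) -> int:
        return self.values.shape[0]

    @property
    def n_isotopes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SourceTable:
    """Per-(source, isotope) normal parameters: means mu_jk and SDs omega_jk."""

    source_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = _as_matrix(self.means, "source means")
        sds = _as_matrix(self.sds, "source sds")
        if means.shape != sds.shape:
            raise ValueError("source means and sds shapes differ")
        if means.shape[0] < 2:
            raise ValueError("need at least two sources")
        if np.any(sds < 0):
            raise ValueError("source sds must be non-negative")
        names = tuple(self.source_names)
        if len(names) != means.shape[0]:
            raise ValueError("source_names length does not match rows")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "source_names", names)

    @property
    def n_sources(self) -> int:
        return self.means.shape[0]

    @property
    def n_isotopes(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class TEFTable:
    """Trophic enrichment factor means lambda_jk and SDs tau_jk (K x J)."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = _as_matrix(self.means, "TEF means")
        sds = _as_matrix(self.sds, "TEF sds")
        if means.shape != sds.shape:
            raise ValueError("TEF means and sds shapes differ")
        if np.any(sds < 0):
            raise ValueError("TEF sds must be non-negative")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @classmethod
    def zeros(cls, n_sources: int, n_isotopes: int) -> "TEFTable":
        """No enrichment, no enrichment uncertainty."""
        z = np.zeros((n_sources, n_isotopes))
        return cls(means=z, sds=z.copy())


@dataclass(frozen=True)
class ConcentrationTable:
    """Fractional elemental concentrations q_jk (K x J), strictly positive."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_matrix(self.values, "concentrations")
        if np.any(arr <= 0):
            raise ValueError("concentrations must be strictly positive")
        object.__setattr__(self, "values", arr)

    @classmethod
    def ones(cls, n_sources: int, n_isotopes: int) -> "ConcentrationTable":
        """Equal concentrations: the concentration-independent model."""
        return cls(values=np.ones((n_sources, n_isotopes)))


@dataclass(frozen=True)
class ProportionVector:
    """Dietary proportions on the K-simplex."""

    p: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.p, dtype=float).ravel()
        if arr.size < 2:
            raise ValueError("need at least two proportions")
        if not np.all(np.isfinite(arr)):
            raise ValueError("proportions must be finite")
        if np.any(arr < 0):
            raise ValueError("proportions must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {arr.sum()}, not 1")
        # renormalize residual float error so downstream sums are exact
        object.__setattr__(self, "p", arr / arr.sum())

    @property
    def k(self) -> int:
        return self.p.size


@dataclass(frozen=True)
class ResidualScale:
    """Per-isotope residual SDs sigma_j (permil)."""

    sigma: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.sigma, dtype=float).ravel()
        if not np.all(np.isfinite(arr)):
            raise ValueError("sigma must be finite")
        if np.any(arr < 0):
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "sigma", arr)


def _check_dims(sources: SourceTable, tefs: TEFTable, conc: ConcentrationTable,
                k: int, j: int | None = None):
    if sources.means.shape[0] != k:
        raise ValueError(
            f"proportion vector has {k} entries but {sources.means.shape[0]} sources"
        )
    if tefs.means.shape != sources.means.shape:
        raise ValueError("TEF table dimensions do not match source table")
    if conc.values.shape != sources.means.shape:
        raise ValueError("concentration table dimensions do not match source table")
    if j is not None and sources.means.shape[1] != j:
        raise ValueError(
            f"data have {j} isotopes but source table has {sources.means.shape[1]}"
        )


def mixture_moments(
    p: ProportionVector,
    sources: SourceTable,
    tefs: TEFTable | None = None,
    conc: ConcentrationTable | None = None,
    sigma: ResidualScale | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal mean and variance of a consumer's isotope values.

    Returns ``(mean, var)``, each of length J.  Source and TEF uncertainty
    enter the variance additively; residual variance ``sigma_j^2`` is added
    on top, so ``var_j >= sigma_j^2`` always.
    """
    K, J = sources.means.shape
    if tefs is None:
        tefs = TEFTable.zeros(K, J)
    if conc is None:
        conc = ConcentrationTable.ones(K, J)
    if sigma is None:
        sigma = ResidualScale(np.zeros(J))
    _check_dims(sources, tefs, conc, p.k)
    if sigma.sigma.size != J:
        raise ValueError("sigma length does not match number of isotopes")

    w = p.p[:, None] * conc.values            # K x J unnormalized weights
    denom = w.sum(axis=0)                     # length J, > 0 by invariants
    mean = (w * (sources.means + tefs.means)).sum(axis=0) / denom
    var = ((w ** 2) * (sources.sds ** 2 + tefs.sds ** 2)).sum(axis=0) / denom ** 2
    var = var + sigma.sigma ** 2
    return mean, var


def log_likelihood(
    data: MixtureObservations,
    p: ProportionVector,
    sigma: ResidualScale,
    sources: SourceTable,
    tefs: TEFTable | None = None,
    conc: ConcentrationTable | None = None,
) -> float:
    """Log-likelihood of the consumer matrix under the marginalized model.

    Consumers are i.i.d. and isotopes independent given the parameters, so
    the result is additive over both.  A zero total variance on an isotope
    is only admissible if every observation sits exactly at the mixture
    mean; otherwise the likelihood is degenerate and an error is raised.
    """
    K, J = sources.means.shape
    _check_dims(sources, tefs if tefs is not None else TEFTable.zeros(K, J),
                conc if conc is not None else ConcentrationTable.ones(K, J),
                p.k, data.n_isotopes)
    mean, var = mixture_moments(p, sources, tefs, conc, sigma)
    x = data.values
    total = 0.0
    for j in range(J):
        resid = x[:, j] - mean[j]
        if var[j] <= 0.0:
            if np.all(resid == 0.0):
                continue  # point mass exactly on the data: density diverges
            raise DegenerateLikelihoodError(
                f"isotope {j}: total variance is zero but data are off the mean"
            )
        total += -0.5 * (
            x.shape[0] * np.log(2.0 * np.pi * var[j])
            + np.sum(resid ** 2) / var[j]
        )
    return float(total)


def _in_hull_lp(point: np.ndarray, vertices: np.ndarray, tol: float = 1e-9) -> bool:
    """Linear feasibility: does a convex weighting of the rows hit *point*?"""
    K = vertices.shape[0]
    A_eq = np.vstack([vertices.T, np.ones(K)])
    b_eq = np.append(point, 1.0)
    res = linprog(np.zeros(K), A_eq=A_eq, b_eq=b_eq, bounds=[(0, 1)] * K,
                  method="highs")
    if res.status == 0:
        return True
    if res.status == 2:
        return False
    # numerical trouble: retry with a slack relaxation
    res = linprog(np.zeros(K), A_eq=A_eq, b_eq=b_eq,
                  bounds=[(-tol, 1 + tol)] * K, method="highs")
    return res.status == 0


def mixing_polygon_check(
    data: MixtureObservations,
    sources: SourceTable,
    tefs: TEFTable | None = None,
) -> np.ndarray:
    """Flag which consumers lie inside the isotopic mixing polygon.

    The polygon is the convex hull of the TEF-corrected source means in
    J-dimensional isotope space.  A consumer outside it cannot be written
    as any convex mixture of the sources; fitting still proceeds, but such
    points indicate missing sources or mis-specified TEFs.  Returns a
    boolean array of length N (True = inside).  Degenerate (e.g. collinear)
    source geometries fall back to a feasibility check on the affine hull,
    with a warning.
    """
    K, J = sources.means.shape
    if tefs is None:
        tefs = TEFTable.zeros(K, J)
    if tefs.means.shape != sources.means.shape:
        raise ValueError("TEF table dimensions do not match source table")
    if data.n_isotopes != J:
        raise ValueError("data isotope count does not match source table")
    corrected = sources.means + tefs.means
    if K < J + 1:
        warnings.warn(
            f"only {K} sources in {J}-D isotope space: mixing polygon is "
            "degenerate; checking membership of the affine hull segment",
            stacklevel=2,
        )
    x = data.values
    if J == 1:
        lo, hi = corrected.min(), corrected.max()
        return (x[:, 0] >= lo - 1e-9) & (x[:, 0] <= hi + 1e-9)
    try:
        hull = ConvexHull(corrected)
    except QhullError:
        warnings.warn(
            "degenerate source geometry (collinear or coincident corrected "
            "means); mixing-polygon check performed on the affine hull",
            stacklevel=2,
        )
        return np.array([_in_hull_lp(xi, corrected) for xi in x])
    # inside iff every facet inequality A.x + b <= 0 holds
    A = hull.equations[:, :-1]
    b = hull.equations[:, -1]
    return np.all(x @ A.T + b <= 1e-9, axis=1)
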