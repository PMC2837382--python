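"""Metropolis-within-Gibbs sampler for the mixing-model posterior.

The target is the joint posterior of the dietary proportions ``p`` (on the
K-simplex) and the per-isotope residual scales ``sigma``:

    posterior(p, sigma | X)  ∝  likelihood(X | p, sigma)
                                × Dirichlet(p | alpha) × prod_j U(sigma_j; 0, upper)

Parameterization
----------------
``p`` is mapped to an unconstrained vector ``f`` through a pinned softmax
(``f_1 = 0`` fixed, K-1 free coordinates), which keeps every retained draw
strictly interior to the simplex.  The change of variables contributes a
log-Jacobian of ``sum_k log p_k``.  Each ``sigma_j`` is sampled on the log
scale; the uniform prior on ``sigma_j`` becomes ``exp(t_j)/upper`` on
``t_j = log sigma_j``, contributing ``t_j`` to the log-target.

Updates are random-walk Metropolis: one joint block for ``f`` and one
single-site block per ``t_j``.  Proposal scales adapt in batches toward a
target acceptance rate during burn-in and are frozen afterwards, so the
retained chain satisfies detailed balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model import (
    ConcentrationTable,
    MixtureObservations,
    ProportionVector,
    ResidualScale,
    SourceTable,
    TEFTable,
)
from .priors import DirichletPrior, SigmaPrior

__all__ = ["MCMCConfig", "PosteriorDraws", "fit"]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and adaptation settings.

    Defaults mirror a production run (200,000 iterations); exploratory and
    test runs use far shorter chains.
    """

    n_iter: int = 200_000
    burn_in: int = 50_000
    thin: int = 15
    seed: int = 0
    target_acceptance: float = 0.35
    adapt_until: int | None = None  # defaults to burn_in

    def __post_init__(self):
        if self.burn_in < 0 or self.n_iter <= self.burn_in:
            raise ValueError("require n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must be in (0, 1)")

    @property
    def adaptation_end(self) -> int:
        return self.burn_in if self.adapt_until is None else self.adapt_until


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws of (p, sigma) plus run metadata."""

    p_draws: np.ndarray          # M x K, each row on the simplex
    sigma_draws: np.ndarray      # M x J, all >= 0
    source_names: tuple[str, ...]
    isotope_names: tuple[str, ...]
    config: MCMCConfig
    acceptance_rates: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.p_draws.shape[0]

    @property
    def n_sources(self) -> int:
        return self.p_draws.shape[1]

    @property
    def n_isotopes(self) -> int:
        return self.sigma_draws.shape[1]


def _softmax_pinned(f_free: np.ndarray) -> np.ndarray:
    """Map K-1 free coordinates to the interior of the K-simplex."""
    f = np.concatenate(([0.0], f_free))
    f = f - f.max()
    e = np.exp(f)
    return e / e.sum()


def fit(
    data: MixtureObservations,
    sources: SourceTable,
    tefs: TEFTable | None = None,
    conc: ConcentrationTable | None = None,
    prior: DirichletPrior | None = None,
    config: MCMCConfig | None = None,
    sigma_prior: SigmaPrior | None = None,
) -> PosteriorDraws:
    """Sample the posterior of dietary proportions and residual scales.

    Identical seed and inputs give identical draws.  Raises if the
    log-posterior is non-finite at the initial state.
    """
    K, J = sources.means.shape
    if tefs is None:
        tefs = TEFTable.zeros(K, J)
    if conc is None:
        conc = ConcentrationTable.ones(K, J)
    if prior is None:
        prior = DirichletPrior(np.ones(K))
    if config is None:
        config = MCMCConfig()
    if sigma_prior is None:
        sigma_prior = SigmaPrior()
    if prior.k != K:
        raise ValueError("prior dimension does not match number of sources")
    if data.n_isotopes != J:
        raise ValueError("data isotope count does not match source table")

    x = data.values
    N = x.shape[0]
    xbar = x.mean(axis=0)
    css = ((x - xbar) ** 2).sum(axis=0)      # centered sum of squares per isotope

    q = conc.values
    A = sources.means + tefs.means            # corrected means, K x J
    V = sources.sds ** 2 + tefs.sds ** 2      # combined spread, K x J
    alpha = prior.alpha
    # Dirichlet density + softmax Jacobian collapse to norm + sum(alpha*log p)
    dir_norm = float(gammaln(alpha.sum()) - gammaln(alpha).sum())
    log_upper = np.log(sigma_prior.upper)

    def moments(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = p[:, None] * q
        denom = w.sum(axis=0)
        mean = (w * A).sum(axis=0) / denom
        mixvar = ((w * w) * V).sum(axis=0) / (denom * denom)
        return mean, mixvar

    def iso_loglik(mean: np.ndarray, var: np.ndarray) -> np.ndarray:
        """Per-isotope log-likelihood from sufficient statistics."""
        return -0.5 * (
            N * np.log(2.0 * np.pi * var)
            + (N * (mean - xbar) ** 2 + css) / var
        )

    # --- initialization: p at the prior mean, sigma at the sample SD ---
    p0 = alpha / alpha.sum()
    f = np.log(p0[1:]) - np.log(p0[0])
    sample_sd = np.sqrt(css / max(N - 1, 1))
    sig = np.clip(sample_sd, 1e-3, sigma_prior.upper * 0.5)
    t = np.log(sig)

    p = _softmax_pinned(f)
    mean, mixvar = moments(p)
    sig2 = np.exp(2.0 * t)
    L = iso_loglik(mean, mixvar + sig2)
    prior_p = dir_norm + float(alpha @ np.log(p))
    if not (np.all(np.isfinite(L)) and np.isfinite(prior_p)):
        bad = "likelihood" if not np.all(np.isfinite(L)) else "proportion prior"
        raise RuntimeError(
            f"non-finite log-posterior at initialization ({bad} term); "
            "check source SDs and data scale"
        )

    rng = np.random.default_rng(config.seed)
    n_iter, burn_in, thin = config.n_iter, config.burn_in, config.thin
    adapt_end = config.adaptation_end
    batch = 50

    scale_f = 0.1
    scale_t = np.full(J, 0.5)
    acc_f_batch = 0
    acc_t_batch = np.zeros(J)
    acc_f_total = 0
    acc_t_total = np.zeros(J)
    post_burn = 0

    keep = range(burn_in, n_iter, thin)
    M = len(keep)
    p_draws = np.empty((M, K))
    sigma_draws = np.empty((M, J))
    keep_idx = 0
    next_keep = burn_in

    # pre-generate innovations: [K-1 for f | J for t] and uniforms [1+J]
    z = rng.standard_normal((n_iter, K - 1 + J))
    u = np.log(rng.random((n_iter, 1 + J)))

    Lsum = float(L.sum())
    for it in range(n_iter):
        # --- joint block update of the free softmax coordinates ---
        f_prop = f + scale_f * z[it, : K - 1]
        p_prop = _softmax_pinned(f_prop)
        mean_prop, mixvar_prop = moments(p_prop)
        L_prop = iso_loglik(mean_prop, mixvar_prop + sig2)
        prior_prop = dir_norm + float(alpha @ np.log(p_prop))
        if u[it, 0] < L_prop.sum() + prior_prop - Lsum - prior_p:
            f, p, mean, mixvar, L, prior_p = (
                f_prop, p_prop, mean_prop, mixvar_prop, L_prop, prior_prop,
            )
            Lsum = float(L.sum())
            acc_f_batch += 1
            if it >= burn_in:
                acc_f_total += 1

        # --- single-site updates of each log residual scale ---
        for j in range(J):
            t_prop = t[j] + scale_t[j] * z[it, K - 1 + j]
            if t_prop >= log_upper:
                continue  # outside the uniform prior's support
            s2_prop = np.exp(2.0 * t_prop)
            Lj_prop = -0.5 * (
                N * np.log(2.0 * np.pi * (mixvar[j] + s2_prop))
                + (N * (mean[j] - xbar[j]) ** 2 + css[j]) / (mixvar[j] + s2_prop)
            )
            if u[it, 1 + j] < Lj_prop - L[j] + t_prop - t[j]:
                t[j] = t_prop
                sig2[j] = s2_prop
                Lsum += Lj_prop - L[j]
                L[j] = Lj_prop
                acc_t_batch[j] += 1
                if it >= burn_in:
                    acc_t_total[j] += 1

        if it >= burn_in:
            post_burn += 1

        # --- batch adaptation of proposal scales during burn-in ---
        if it < adapt_end and (it + 1) % batch == 0:
            delta = min(0.25, (batch / (it + 1)) ** 0.5)
            scale_f *= np.exp(delta * (acc_f_batch / batch - config.target_acceptance))
            scale_t *= np.exp(delta * (acc_t_batch / batch - config.target_acceptance))
            acc_f_batch = 0
            acc_t_batch[:] = 0

        if it == next_keep:
            p_draws[keep_idx] = p
            sigma_draws[keep_idx] = np.exp(t)
            keep_idx += 1
            next_keep += thin

    denom = max(post_burn, 1)
    rates = {"p": acc_f_total / denom}
    for j, name in enumerate(data.isotope_names):
        rates[f"sigma[{name}]"] = float(acc_t_total[j]) / denom

    return PosteriorDraws(
        p_draws=p_draws,
        sigma_draws=sigma_draws,
        source_names=tuple(sources.source_names),
        isotope_names=tuple(data.isotope_names),
        config=config,
        acceptance_rates=rates,
    )
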