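"""Summaries and diagnostics of posterior draws.

Central tendency includes the marginal posterior mode (located by kernel
density estimation), since dietary-proportion posteriors are often skewed
and the mode is the natural single-number summary to carry into downstream
models.  Note that marginal modes need not sum to unity — only full draws
respect the simplex constraint, so downstream analyses that can consume the
whole posterior should.

Intervals are equal-tailed quantile intervals.  The K x K correlation
matrix of the proportion draws is the main trade-off diagnostic: a strong
negative correlation between two proportions means the data cannot separate
those sources — one is simply traded off against the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .sampler import PosteriorDraws

__all__ = [
    "PosteriorSummary",
    "credible_interval",
    "posterior_mode",
    "proportion_correlations",
    "summarize",
]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter table of mean, sd, mode and quantiles."""

    table: pd.DataFrame  # index: parameter names; columns: mean, sd, mode, q*
    level: float

    def __str__(self) -> str:
        return (
            f"Posterior summary ({self.level * 100:g}% equal-tailed intervals)\n"
            + self.table.to_string(float_format=lambda v: f"{v:.4f}")
        )


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval at quantiles (1-level)/2 and 1-(1-level)/2."""
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least two draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo, hi = np.quantile(arr, [(1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0])
    return float(lo), float(hi)


def posterior_mode(draws) -> float:
    """Marginal mode via Gaussian KDE (Silverman bandwidth, 512-point grid)."""
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 30:
        raise ValueError("need at least 30 draws for a stable mode estimate")
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        return float(lo)
    kde = gaussian_kde(arr, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def proportion_correlations(draws: PosteriorDraws) -> pd.DataFrame:
    """K x K correlation matrix of the proportion draws.

    Zero-variance components produce NaN rows/columns with a warning rather
    than being silently zeroed.
    """
    p = draws.p_draws
    if p.shape[0] < 2:
        raise ValueError("need at least two draws")
    sd = p.std(axis=0)
    degenerate = sd == 0.0
    if np.any(degenerate):
        names = [draws.source_names[k] for k in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance proportion draws for {names}; correlations "
            "undefined (NaN) for those sources",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(p, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return pd.DataFrame(corr, index=draws.source_names, columns=draws.source_names)


def summarize(draws: PosteriorDraws, level: float = 0.95) -> PosteriorSummary:
    """Tabulate mean, sd, mode and quantiles for every p_k and sigma_j."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cols = np.hstack([draws.p_draws, draws.sigma_draws])
    names = [f"p[{s}]" for s in draws.source_names] + [
        f"sigma[{i}]" for i in draws.isotope_names
    ]
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    rows = []
    for v in cols.T:
        lo, hi = credible_interval(v, level)
        rows.append(
            {
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "mode": posterior_mode(v) if v.size >= 30 else float(np.median(v)),
                **{f"q{q * 100:g}": float(np.quantile(v, q)) for q in qs},
                "lower": lo,
                "upper": hi,
            }
        )
    table = pd.DataFrame(rows, index=names)
    return PosteriorSummary(table=table, level=level)
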