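# Methods

## Model

A consumer's δ-value on isotope `j` is modelled as a convex mixture of `K`
source values shifted by trophic enrichment, with the source (`s_jk`) and
TEF (`c_jk`) uncertainty marginalized out so that, conditional on the
dietary proportions `p` and residual scales `σ`, every observation is
normal:

```
X_ij ~ N(mean_j, var_j)
mean_j = Σ_k p_k q_jk (μ_jk + λ_jk) / Σ_k p_k q_jk
var_j  = Σ_k p_k² q_jk² (ω_jk² + τ_jk²) / (Σ_k p_k q_jk)² + σ_j²
```

Assumptions: source and TEF distributions are normal; isotopes are
conditionally independent given the parameters (diagonal covariance, one
residual scale per isotope); consumers are i.i.d.; no isotopic routing
(every source's elements are assimilated equally, up to the optional
concentration weights `q_jk`). The concentration-weighted ratio form is the
standard concentration-dependent extension; it reduces exactly to the plain
weighted sums when all `q_jk` are equal, and is invariant to rescaling any
isotope's concentration column (only relative concentrations matter).

The residual term `σ_j` is deliberate: errors on the observed data beyond
what source and TEF spread explain (physiology, unidentified minor sources)
should not be forced into the other variance components. Omitting it is
equivalent to asserting the model is complete, which real dietary data
rarely justify.

Zero-mean, zero-SD TEFs are exactly equivalent to omitting TEFs; a nonzero
TEF mean only translates the data in isotope space. Both facts are asserted
by tests.

## Priors

- `p ~ Dirichlet(α)`, default `α = (1, …, 1)`: uniform over the simplex,
  prior mean `1/K`, prior variance `(K−1)/(K²(K+1))`. Informative priors
  are elicited from target means plus a single SD on the first proportion
  by inverting the Dirichlet moment formulas
  (`α_0 = m_1(1−m_1)/sd² − 1`, `α_k = m_k α_0`); one SD is all a Dirichlet
  can absorb, so per-source uncertainties are not supported. The requested
  SD must satisfy `sd² < m_1(1−m_1)` or no Dirichlet exists.
- `σ_j ~ Uniform(0, upper)` with default `upper = 20 ‰`. The functional
  form of a merely "vague" scale prior is a genuine design choice; a
  bounded uniform keeps the posterior proper, is flat over every plausible
  residual scale for δ-value data (single-digit ‰), and is dominated by the
  likelihood in all tested regimes. `upper` is configurable per analysis.

## Sampler

Metropolis-within-Gibbs random-walk sampling, with `p` parameterized by a
pinned softmax (`f_1 = 0`, `K−1` free coordinates) and `σ_j` on the log
scale. The softmax keeps every retained draw strictly interior to the
simplex; its Jacobian (`Σ_k log p_k`) is included in the target — omitting
it would silently change the prior. The uniform σ prior contributes
`t_j = log σ_j` on the log scale plus a hard bound at `upper`.

Updates per iteration: one joint Gaussian random-walk block for the free
softmax coordinates and one single-site update per `log σ_j` (which touches
only that isotope's likelihood term, making σ updates cheap). Proposal
scales adapt in batches of 50 toward an acceptance rate of 0.35 with a
Robbins–Monro decaying step, and freeze at the end of burn-in so the
retained chain satisfies detailed balance. Initialization is `p` at the
prior mean and `σ_j` at the sample SD of the data column (clipped to
`[10⁻³, upper/2]`), which gives a finite log-posterior for any valid
input; a non-finite initial target raises immediately, naming the offending
term.

Defaults are production-scale (200,000 iterations, 50,000 burn-in, thin
15). The test-suite and acceptance runs use 10,000–50,000 iterations with a
quarter burn-in — at the data sizes involved (N ≈ 10, J ≤ 3) the integrated
autocorrelation is short and these chains reproduce deterministic grid
quadrature within Monte-Carlo error, which is itself one of the tests.
Identical seed and inputs give bit-identical draws.

## Summaries

Equal-tailed quantile intervals throughout (deterministic, trivially
oracle-checkable); HPD intervals are a non-goal. The marginal mode is
located by Gaussian KDE with Silverman bandwidth on a 512-point grid over
the draw range — posteriors on proportions are often skewed, making the
mode the preferred single-number summary, but marginal modes need not sum
to one (only full draws respect the simplex), so downstream analyses should
consume whole draws where possible. The K×K correlation matrix of the
proportion draws is the trade-off diagnostic: for `K = 2` it is exactly −1
by closure, and in general a strong negative entry means the data cannot
isolate either source's contribution. Zero-variance components yield NaN
entries with a warning rather than silent zeros.

The mixing-polygon check (convex hull of TEF-corrected source means, via
Qhull with a linear-programming fallback on degenerate geometries) runs
before CLI fits: consumers outside the polygon cannot be expressed as any
convex mixture and are reported, though fitting proceeds regardless.

## Synthetic-data generators

The generators define the package's validation conditions and are
first-class, tested code.

- **Scenario 1 (well-specified):** `p ~ Dirichlet(1)`; `μ ~ N(0, 10)`;
  `ω ~ |N(0, 2)|`; `λ ~ N(0, 1)`; `τ ~ |N(0, 1)|`; `σ ~ |N(0, 1)|`
  (half-normal = absolute value of the stated normal); consumers drawn
  from the marginalized model above with equal concentrations. N = 10
  consumers per dataset.
- **Scenario 2 (heavy tails):** identical parameter draws, but per-consumer
  source values, TEF values and residuals use `location + scale·t₄` —
  long-tailed errors of the sort produced when source/TEF spreads rest on
  very few observations. The fitted model still assumes normality.
- **Scenario 3 (aggregated sources):** data generated from K sources; the
  two closest in Euclidean mean-isotope distance are combined before
  fitting, and the merged truth is the sum of the two proportions. The
  merged source carries the pooled-population moments — mean
  `(μ_a+μ_b)/2`, variance `(ω_a²+ω_b²)/2 + (μ_a−μ_b)²/4` — i.e. exactly
  what measuring the combined tissue samples as a single source would
  yield, so between-source spread appears in the merged SD. Averaging the
  printed SDs instead would fabricate a source table no sampling protocol
  produces and understate the combined spread; with that convention
  coverage at K=3, J=2 drops to ≈ 0.68, versus ≈ 0.86 for the pooled
  moments.
- **Worked example:** K=3, J=2, N=10; TEFs zero; equal concentrations;
  true p = (0.75, 0.2, 0.05); residual σ of 0.1 or 0.5. The source
  geometry is a well-separated triangle with corrected means (−5,−5),
  (5,−5), (0,5) and ω = 0.5 on both isotopes — chosen so the 3-source /
  2-isotope system is exactly determined up to noise; recovery is robust
  to any similarly separated triangle. Note the generating mean lies 0.5 ‰
  from the polygon's lower edge while consumer SD ≈ 0.4 ‰, so individual
  consumers occasionally fall just outside the polygon.

What these generators do **not** emulate about real data: correlated
isotopes, consumer covariates or group structure, isotopic routing,
non-normal *fitted* models, and source tables estimated from finite samples
(source means here are known exactly to the generator). Passing tests
therefore demonstrate calibration and robustness of the inference
machinery, not that any particular field dataset satisfies the model.

## Coverage study

For each (scenario, K, J) cell, `run_coverage` generates `n` datasets,
fits each with the flat prior, and scores the fraction of true proportions
inside their equal-tailed 95% intervals, with binomial standard errors
`√(c(1−c)/n_checks)`. Per-dataset seeds are spawned from the master seed
via `SeedSequence` spawn keys, so any cell or dataset is independently
reproducible. Failed fits are counted and reported, never silently
dropped. Because scenario 1 draws its truth from the same Dirichlet the
model uses as prior and the observation model matches the generator,
nominal coverage is the expected outcome for a correct implementation —
that is the headline calibration property. The desk-scale study (100
datasets, 10,000-iteration fits) shows mild over-coverage (~96–98%),
consistent with nominal within its binomial noise.

## Numerical choices

- Likelihood evaluated from per-isotope sufficient statistics (column
  means and centered sums of squares), so each MCMC proposal costs O(KJ).
- Simplex sums are renormalized once at construction; retained draws
  satisfy `Σp = 1` to machine precision.
- Dirichlet boundary density: `−inf` (not an exception) when a zero
  component has `α_k ≠ 1`.
- CSV output uses `%.17g` and reading uses round-trip float parsing, so
  generated datasets round-trip bit-exactly.
- Degenerate inputs: zero total variance with data off the mixture mean
  raises a dedicated degenerate-likelihood error; collinear source
  geometries route the polygon check through an LP on the affine hull.

## Limitations

- Single consumer group; no hierarchical/random-effects structure.
- Diagonal residual covariance across isotopes.
- Equal-tailed (not HPD) intervals; no convergence diagnostics beyond
  acceptance rates (ESS is used in tests via arviz).
- The scenario-3 merge convention and the σ prior form are declared design
  choices where the underlying protocol is ambiguous; both are documented
  above and exercised by tests.
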