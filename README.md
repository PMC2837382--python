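# isomix

Bayesian stable-isotope mixing models for source partitioning.

Ecologists (and pollution-tracing researchers) routinely need to know what
fraction of a mixture came from each of several candidate sources: which prey
make up a consumer's diet, or which origins feed a contaminant plume. Stable
isotope δ-values make this tractable because consumer tissue is, to first
order, a proportion-weighted blend of its sources. But natural systems are
noisy — sources vary, trophic enrichment factors (TEFs) are uncertain, and
consumers differ for reasons the sources cannot explain — and they are often
*underdetermined*: more sources than isotopes + 1, so no unique algebraic
solution exists. `isomix` treats the problem as Bayesian inference, returning
full posterior distributions over the dietary proportions that quantify which
of the many feasible solutions are probable.

## The model

For `N` consumers measured on `J` isotopes with `K` sources:

- `X_ij` — observed δ-value of isotope `j` on consumer `i`;
- `s_jk ~ N(μ_jk, ω_jk²)` — source isotope values;
- `c_jk ~ N(λ_jk, τ_jk²)` — TEFs (diet-to-tissue offsets);
- `q_jk` — elemental concentration of element `j` in source `k`;
- `p_k` — dietary proportions on the simplex (estimated);
- `σ_j` — residual SD for inter-consumer variance the sources cannot
  explain (estimated).

Marginalizing the source and TEF uncertainty, each observation is normal with

```
mean_j = Σ_k p_k q_jk (μ_jk + λ_jk) / Σ_k p_k q_jk
var_j  = Σ_k p_k² q_jk² (ω_jk² + τ_jk²) / (Σ_k p_k q_jk)² + σ_j²
```

(with equal concentrations the weights reduce to the plain `p_k` sums).
The prior on `p` is Dirichlet — by default flat (`α = 1`, prior mean `1/K`,
prior variance `(K−1)/(K²(K+1))`), or elicited from target means plus one
SD. Residual scales get a bounded-uniform prior. Fitting is by
Metropolis-within-Gibbs on a softmax transform of the simplex, with proposal
scales adapted during burn-in.

## Worked example

Simulate the bundled two-isotope example — 10 consumers drawing on three
well-separated sources with true proportions 0.75 / 0.20 / 0.05 and residual
SD 0.1 — then fit it:

```sh
isomix simulate --scenario figure1 --sigma 0.1 --seed 42 --out fig1
isomix fit --consumers fig1_consumers.csv --sources fig1_sources.csv \
           --iterations 20000 --burnin 5000 --thin 5 --seed 1 --out run
```

which prints

```
Posterior summary (95% equal-tailed intervals)
              mean     sd   mode   q2.5    q25    q50    q75  q97.5  lower  upper
p[A]        0.7466 0.0156 0.7441 0.7167 0.7360 0.7464 0.7572 0.7780 0.7167 0.7780
p[B]        0.2128 0.0159 0.2168 0.1816 0.2022 0.2129 0.2232 0.2434 0.1816 0.2434
p[C]        0.0407 0.0143 0.0378 0.0124 0.0310 0.0403 0.0502 0.0689 0.0124 0.0689
sigma[iso1] 0.1832 0.1382 0.0664 0.0082 0.0736 0.1557 0.2669 0.5184 0.0082 0.5184
sigma[iso2] 0.2065 0.1601 0.0848 0.0072 0.0842 0.1704 0.2946 0.6066 0.0072 0.6066
```

All three generating proportions sit inside their 95% intervals, and the
posterior means land within ~0.02 of the truth. The run also writes the raw
draws (`run_draws.csv`), a JSON summary (`run_summary.json`) and the K×K
posterior correlation matrix of the proportions (`run_correlations.csv`) —
strongly negative entries there flag pairs of sources the data cannot
separate, one simply trading off against the other. Consumers falling
outside the mixing polygon (the convex hull of TEF-corrected source means)
are warned about on stderr before fitting.

A calibration study — simulate many datasets with known proportions, fit
each, and count how often the truth falls inside the 95% intervals — runs
with:

```sh
isomix coverage --scenario 1 --n-datasets 100 --k-range 3 --j-range 2 \
                --iterations 10000 --seed 0 --out coverage.csv
```

`--scenario 2` swaps every error term for a scaled Student-t₄ and
`--scenario 3` merges the two closest sources before fitting, probing the
model's robustness when its assumptions are violated.

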