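# Methods

## Scientific problem

Cell-type-resolved RNA-seq catalogues pool samples from many studies.  Each
study measures its own gene panel (so absence of a (sample, gene) pair is
structured missingness, not a zero), uses its own protocol (so each dataset
shifts every gene's apparent abundance by a study-specific amount), and
contributes unequal numbers of samples (so naive per-cell-type means are
dominated by the largest studies).  The package estimates cell-type transcript
abundances that are freed of these study effects, regenerates a harmonized
count table from the fitted model, and quantifies the downstream benefit for
signature-based deconvolution.

## Model

Let `Y[s, g]` be the count of gene `g` in sample `s`, with cell type `c(s)`,
dataset `r(s)` and known exposure `eps[s]`.  Writing `NB(mu, theta)` for the
negative binomial with mean `mu` and overdispersion `theta`
(`var = mu + mu^2 / theta`):

```
Y[s, g]     ~ NB( exp(alpha[g, c(s)] + beta[g, r(s)] + eps[s]),  exp(sigma[g]) )
beta[g, r]  ~ Normal(0, rho[g])                  # dataset random intercepts
rho[g]      ~ Gamma(omega, o)                    # shape-rate; shrinkage across genes
sigma[g]    ~ Normal(lambda0 + lambda1 * abar[g], delta)
alpha[g, c] ~ SkewNormal(mu, exp(psi), upsilon)  # Azzalini parameterization
```

where `abar[g] = mean_c alpha[g, c]` is the gene's mean expected log
abundance.  The `sigma` trend captures the well-known association between a
gene's mean abundance and its overdispersion; since `sigma` is per gene while
`alpha` is per (gene, cell type), the gene-level mean `abar` is used as the
trend covariate.  Unobserved (sample, gene) pairs are omitted from the
likelihood — exactly the right treatment for missingness caused by
nonoverlapping gene panels, because the missingness mechanism does not depend
on the unobserved counts given the design.

Hyperpriors on `(lambda0, lambda1, delta, mu, psi, upsilon)` are normal,
centered on constants estimated outside the model (below), with SD equal to
20% of the constant's magnitude, floored at 0.05 so near-zero centers never
degenerate.  `omega` and `o` have Normal(3, 1) priors constrained to exceed 1.

### Exposure

`eps[s]` is the centered log effective library size, `log(TMM[s] * L[s])`,
where `L` is the library size and `TMM` the trimmed-mean-of-M-values
normalization factor (30% two-sided trim on M, 5% on A, delta-method precision
weights, reference chosen by the 75th-percentile count fraction, factors
scaled to unit geometric mean).  Exposure is data, not a parameter.

### Hyperprior constants

Per (gene, cell type) group with at least two exposure-corrected observations,
the sample mean `m` and variance `v` give a moment estimate
`theta = m^2 / (v - m)` when `v > m`.  Ordinary least squares of `log theta`
on `log m` yields `(lambda0*, lambda1*)` and residual SD `delta*`.  A
skew-normal ML fit to the pooled group log-means yields
`(mu*, psi*, upsilon*)`; when the ML fit degenerates to a boundary solution
(|shape| > 10, which happens on small catalogues), a moment fit with sample
skewness capped at the value implied by |shape| = 10 is used instead —
uncapped shapes make the skew-normal prior a numerically hard half-line
barrier.  Note the shape parameter near zero is weakly identified in
principle: the shape-to-skewness map is cubically flat at 0, so on symmetric
data the fitted *shape* scatters widely while the fitted *skewness* stays near
zero; tests therefore check the implied skewness.

### Inference

Posterior sampling is a from-scratch no-U-turn sampler (NUTS): multinomial
sampling over doubling trajectories, divergence declared when the Hamiltonian
error exceeds 1000, dual-averaging step-size adaptation to a 0.8 acceptance
target, and diagonal mass-matrix estimation over doubling warmup windows.
Gradients of the joint log density are analytic and checked against finite
differences.  Sampling is on an unconstrained scale:

- `beta = rho * btilde` with `btilde ~ Normal(0, 1)` (non-centered, which
  removes the funnel between `rho` and `beta`),
- `rho = exp(t)`, `delta = exp(d)`, `omega = 1 + exp(uw)`, `o = 1 + exp(uo)`,
  with the corresponding log-Jacobian terms.

Defaults are 4 chains, 300 warmup and 500 sampling iterations; the validation
studies use 2 chains x 300/300 to fit single-CPU budgets.  With 2000 draws the
2.5% quantile of a posterior summary rests on exactly 50 tail draws.

## Adjusted (study-effect-free) counts

For each raw sample `s` (cell type `c`, exposure `eps[s]`) and gene `g`,
posterior-predictive counts are drawn from
`NB(exp(alpha[g, c]^(d) + eps[s]), exp(sigma[g]^(d)))` over posterior draws
`d` — the dataset intercepts `beta` are deliberately excluded.  Each emitted
count is constrained to the central 80% credible interval of that marginal
(estimated from 400 Monte-Carlo draws): rejection sampling up to 1000 redraws,
then clamping to the nearest bound (or direct clamping with `mode="clamp"`).
One generated sample is emitted per raw sample, reusing its exposure, so
library-size structure is preserved while study structure is removed.  Genes
never observed for a cell type are generated from the prior-informed posterior
and are reported in `prior_only_genes`.

## Synthetic catalogues

`simulate_catalogue` draws forward from the same generative structure:
skew-normal `alpha`, normal dataset intercepts of SD `dataset_sd`, the
`(lambda0, lambda1, delta)` trend for `sigma`, log-normal library sizes, NB
counts via the gamma-Poisson mixture, and structured missingness that deletes
whole (gene, dataset) blocks.  `samples_per_dataset` may be a list, producing
catalogues dominated by one large study.  `planted_shift_log_fold > 0`
replaces the random intercepts with a deterministic `±shift/2` pattern whose
sign alternates with `(gene index + dataset index)` parity.  The parity matters:
a shift with the same sign for all genes in a dataset is indistinguishable
from sequencing depth and would be absorbed into the exposure by TMM, leaving
nothing for the model (or any method) to remove.

## Variance decomposition for the adjustment study

The between-dataset variance share of a gene is computed on `log1p` CPM
(depth must be normalized out first, because adjusted samples deliberately
preserve their source library sizes): within each (gene, cell type) stratum a
one-way ANOVA by dataset is pooled across the gene's strata and converted to
method-of-moments variance components with the between component truncated at
zero; the share is `var_between / (var_between + var_within)`.  Unlike a raw
sum-of-squares ratio — whose chance level is `(R-1)/(n-1)`, about 0.16 at the
study's sizes, making a "below 20% of raw" criterion unattainable for any
method — this estimator is unbiased near zero under exchangeability.

## Validation studies (`sparsesig.experiments`)

All three use fixed simulated catalogues; the sampler seed is caller-supplied.

1. **Recovery** — `G=50, C=3, R=4`, 5 samples/dataset, `dataset_sd=0.5`, 20%
   missingness.  The fit receives the simulation's true exposure: exposure is
   given data in the model, and at a 50-gene panel TMM estimation itself adds
   ~0.4 SD of small-panel noise that would measure the normalizer, not the
   estimator (real catalogues have >20k genes).  Reported: Pearson r between
   posterior-mean and true `alpha` over 150 pairs, and 95% credible-interval
   coverage.  Typical values: r ≈ 0.96, coverage ≈ 0.95.
2. **Adjustment** — `G=40, C=3, R=4`, 12 samples/dataset, planted `log(4)`
   parity shift, 25% missingness.  Reported: fraction of genes whose adjusted
   between-dataset share falls below 20% of the raw share (typically > 0.9;
   raw median share ≈ 0.8, adjusted ≈ 0).
3. **Benchmark** — `G=80, C=3, R=4`, samples `[20, 4, 4, 4]` (one dominant
   study), `dataset_sd=1.0`, 25% missingness.  Signatures of 30 markers ranked
   by second-fold-change are built from raw and adjusted counts; 100
   Dirichlet(1) mixtures are synthesized from the true profiles (column-scaled
   to the same CPM convention as the signatures) and deconvolved by linear
   least squares with clipping and renormalization.  Reported: number of
   mixtures where the adjusted signature has lower mean absolute error
   (typically ≈ 99/100).

## Numerical choices

- NB log-pmf via log-gamma functions; its Poisson limit at `theta = 1e6`
  agrees with the Poisson pmf within 1e-4 on the probability scale (the
  log-pmf error grows like `n^2 / (2 theta)` in the far tail where the mass is
  negligible).
- The skew-normal gradient's inverse Mills ratio switches to the asymptotic
  expansion `-s - 1/s` below `s = -30` to avoid overflow in extreme leapfrog
  states.
- Log-mean linear predictors are clipped at ±40 inside the sampler (means
  beyond `exp(40)` are outside any count's support).

## Limitations

- LLSR deconvolution is an intentionally simple baseline (ordinary least
  squares with clipping); it is outlier-sensitive and not a state-of-the-art
  deconvolution method.
- The NUTS implementation adapts a diagonal mass matrix only; posteriors with
  strong parameter correlations sample less efficiently than with a dense
  metric.
- Hyperprior constants are plug-in point estimates; their uncertainty is only
  partially propagated through the 20% prior SD convention.
- The variance-share criterion assumes dataset labels partition samples into
  at least two groups per gene after missingness.
- Validation studies run at deliberately small problem sizes to fit single-CPU
  budgets; posterior summaries at these sizes carry Monte-Carlo noise of a few
  percent (recovery r varies roughly ±0.01 across sampler seeds, and the
  adjustment study's passing-gene fraction varies about ±0.04 because the
  per-gene variance-share estimator has a heavy right tail at ~40 samples per
  gene — the failing genes differ from seed to seed while the median adjusted
  share stays at zero).
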