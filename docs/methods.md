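# Methods

This note documents the statistical models implemented in `sterilecount`,
the assumptions behind them, the synthetic-data generator that stands in for
field data, and the numerical and design choices a user should know about
before trusting (or extending) the results.

## The data and the estimation problem

A chemical hybridizing agent (CHA) is sprayed on wheat genotypes grown in a
randomized complete block design to induce male sterility for hybrid seed
production. Efficacy is assayed by bagging heads (five per genotype-by-block
plot) under pollen-impermeable bags and counting the seeds that form by
self-pollination: zero seeds means complete sterilization, and a healthy
head would carry roughly 30. The resulting counts are severely
zero-inflated (roughly 40–65% zeros), right-skewed, and unbalanced because
bags are lost to wind.

Two questions drive the analysis: *does sterility differ among genotypes?*
(a screening question, answered with a binary threshold model) and *how many
seeds does a genotype set when sterilization is incomplete, and how often is
it completely sterilized?* (an estimation question, answered with mixture
count models).

## Model ladder

All models share the linear predictor

```
eta_ijk = alpha_i + b_j + u_ij
```

with one fixed effect per genotype (cell-means coding, so `alpha_i` *is* the
genotype's link-scale estimate), a block random intercept
`b_j ~ N(0, sigma_b^2)` and a whole-plot (genotype-by-block experimental
unit) random intercept `u_ij ~ N(0, sigma_ab^2)`, both optional. The bagged
heads within a plot are subsamples sharing `u_ij`.

| family | response | estimation | link |
|---|---|---|---|
| gaussian | raw or transformed counts | REML | identity |
| poisson / negbin | counts | ML (Laplace or AGQ) | log |
| zinb / hnb | counts | ML (Laplace or AGQ) | log (mean), logit (inflation) |
| binary_logit / binary_probit | success = count ≤ threshold | ML (AGQ default) | logit / probit |

The transformations are `log(y+1)`, `sqrt(y+3/8)` and `y^(2/3)`; their
estimates are *naively* back-transformed (no bias correction), with
delta-method standard errors available. This deliberately mirrors the
conventional practice whose failure modes — nonsensical negative counts and
understated uncertainty — the coverage study quantifies; negative
back-transformed values are flagged, never silently corrected.

The negative binomial is NB2: mean `lam`, dispersion `k`, variance
`lam + lam^2/k`, Poisson as the `k -> inf` limit. The zero-inflated model
mixes a structural zero (probability `pi`) with the full NB; the hurdle
model puts probability `pi` on zero exactly and a zero-truncated NB on the
positives. `pi` may be shared (`single`) or genotype-specific
(`per_genotype`); random effects enter the log of the count mean and are
shared between mixture components.

A structural fact worth knowing: with per-genotype `pi`, the zero cell is
saturated in both mixtures, so the ZINB and HNB likelihoods factor
identically (Bernoulli zero part × truncated-NB positive part) and the two
fits share `alpha` and `k`; they differ in what `pi` means and in what one
reports as "the genotype's seed count".

## Marginal likelihood: Laplace and adaptive Gauss–Hermite

Random effects are integrated out either by a joint Laplace approximation
(per-block Newton mode-finding with the exact arrow-structured Hessian and
`log det` correction) or by adaptive Gauss–Hermite quadrature: one level is
integrated directly on mode-centered, curvature-scaled nodes; the nested
block + whole-plot design is handled by adaptive quadrature of each
whole-plot integral inside the block integral (plots are conditionally
independent given the block effect). A variance component at numerical zero
(`sigma^2 < 1e-12`) collapses its integral exactly to the conditional sum.

Accuracy, measured against a dense non-adaptive 41–101-node oracle on toy
data: AGQ with 21 nodes is exact to machine precision; Laplace is exact to
`~5e-4` in its quadratic regime (e.g. `sigma_b^2 = 1/16`, 5 Bernoulli
observations per block) but its error is genuinely `~5e-3` at
`sigma_b^2 = 0.25` with 3–5 Bernoulli observations per block — that is the
approximation, not a bug, and it is why the threshold models default to AGQ.

The optimizer is bounded L-BFGS-B on a transformed space (log variances,
log `k`, logit `pi`) with finite-difference gradients (`ftol 1e-11`), up to
four deterministic restart perturbations for mixture families, and a
central-difference Hessian at the optimum for Wald covariances.
Non-convergence is reported (`converged=False`), never raised; parameters at
bounds or with exploding variance are flagged non-estimable, which is
exactly what happens for per-genotype-`pi` mixtures with one observation
per genotype, or an all-zero response.

Fit statistics: `AICc = -2l + 2p + 2p(p+1)/(n-p-1)` with `n` = number of
heads (a convention choice, recorded because software differs), `BIC`,
`-2LL`, and the Pearson `chi^2/d.f.` overdispersion ratio with the family's
data-scale variance function. Transformed-scale fits are never ranked
against count likelihoods.

The Type III genotype test is a Wald-type F on the genotype contrasts with
containment-style denominator df (`(G-1)(J-1)` when the whole-plot term is
present, residual df otherwise). Operating characteristics, measured by
simulation: nominal type-I error (0.047 at alpha=0.05) at ~100 heads per
genotype, but *conservative* (~0.02) at the field design size of 20 heads
per genotype — a known small-sample property of Wald joint tests (the
statistic was verified against an independent implementation); power for a
0.2-vs-0.95 proportion contrast at 20 heads/genotype exceeds 0.95.

## Synthetic-data generator

`generate_crossing_block` draws from the zero-inflated (or hurdle) NB
process per genotype × block × head with optional log-scale normal block
and whole-plot effects, then deletes records independently with the
bag-loss probability (loss is missing-completely-at-random; the field
mechanism — wind — gives no reason for anything else). Identical config and
seed give a byte-identical dataset.

`paper_like_config` pins the generator to the published study conditions:

* **2015**: the 26 published per-genotype hurdle estimates of `lambda`
  (2.557–25.749) and `pi` (0.119–0.668); NB dispersion `k ≈ 1.98` solved so
  the pooled variance of the implied mixture equals the published 65.1;
  bag loss `1 - 371/520` so the expected sample size is 371.
* **2016**: no per-genotype values are published, so a single
  `(pi, lambda, k) ≈ (0.475, 4.95, 0.476)` is root-solved from the three
  published aggregates (mean 2.6, zero proportion 0.64, variance 35.8) and
  shared by all 26 genotypes; bag loss gives expected n = 182.

Known infidelities, hence what passing tests do and do not show: the 2015
`pi` values are hurdle estimates reused as zero-inflated mixture weights, so
the implied pooled zero proportion (~0.42) slightly exceeds the observed
0.38 and the implied pooled mean (~5.25) sits below the observed 5.7; the
2016 configuration has no genotype heterogeneity at all. The generator also
has no spatial field structure, no weather covariates, and no pollination
model. Tests passing on these data certify the estimation machinery and the
relative behaviour of the models, not field-level agronomic conclusions.

## Coverage study

Each simulated experiment is one crossing block (default: genotypes × 4
blocks × 5 heads, no bag loss, no random effects — an i.i.d. Bernoulli + NB
process). Every model in the ladder is fitted (whole-plot terms dropped, as
is standard for such simulations), a nominal 95% interval is built for each
genotype's seed-count estimate, and a binary indicator records whether the
generating value is inside (endpoints inclusive). Non-convergent fits are
excluded from the denominator with the count reported, so the
scored-as-zero convention can be reconstructed.

Three conventions matter and are explicit in the configuration:

* **Truth**: by default the genotype count-mean parameter `lambda_g` that
  was set in the simulation (`truth="lambda"`); the process mean
  `(1-pi_g) lambda_g` is available as `truth="data_scale_mean"`.
* **Estimand per model**: the back-transformed LS-mean for
  (transformed-)Gaussian rows; `exp(alpha_g)` for Poisson, NB and ZINB (for
  ZINB this is exactly the `lambda` parameter); the model-implied data-scale
  mean `(1-pi) lambda / (1 - f(0))` for the hurdle row. The hurdle's
  structural-zero probability is misspecified under a zero-inflated process
  (it absorbs the NB zeros), which is precisely the failure the study
  exposes; reporting its component mean instead would be consistent for
  `lambda` and show nothing.
* **Intervals**: count models use symmetric data-scale Wald intervals
  (estimate ± z·SE, SE delta-propagated to the data scale); transformed rows
  back-transform the link-scale bounds, with a delta-method-SE variant
  reported alongside. The reported `sd_coverage` is the binary indicator's
  SD, `sqrt(p(1-p))`; `se_mc` is the experiment-clustered Monte-Carlo SE.

Representative results with the 2015-parameterized generator (150
experiments, 26 genotypes, seed 1): ZINB 92.1%, plain NB 53.3%, hurdle NB
40.2%, log-transform 7.2% (delta-variant ~4%), i.e. only the model matching
the generating process delivers its nominal coverage, and misspecification
costs between half and essentially all of it. When the fitted family
matches the generator (Gaussian/Gaussian, ZINB/ZINB at large n), empirical
coverage sits within Monte-Carlo error of 95% — the machinery itself is
calibrated.

## Problem sizes used by the shipped checks

The test suite runs the coverage comparison at 100 experiments on a
lambda-stratified 8-genotype subset of the 2015 parameters, parameter
recovery at n = 500–2000 across a (pi, lambda, k) grid, calibration at
120–200 experiments, and the threshold operating characteristics at 500
null and 200 power replicates. `scripts/acceptance.py` runs the full
26-genotype coverage study at 150 experiments. These sizes are the
package's chosen defaults; every entry point takes `n_experiments`/rep
counts for larger runs (e.g. two seeded batches of 500 to mirror a full
1000-experiment study).

## Known limitations

* Wald (not profile or bootstrap) uncertainty throughout; boundary
  estimates (complete separation, `pi` at 0/1) are flagged, not corrected —
  no Firth-type adjustment, by design.
* REML log-likelihoods of transformed-response fits are not comparable
  across transformations or to count likelihoods; the comparison table
  marks them so.
* Combined across-year models (year fixed effects, genotype-by-year
  interaction) are out of scope.
* The coverage study's published reference values depend on a simulation
  parameter set distributed only in supplementary materials; with the
  published per-genotype tables substituted, the qualitative pattern and
  the ZINB/NB magnitudes reproduce closely, while the hurdle and
  log-transform rows land higher than the reference (0.40 vs 0.20, 0.07 vs
  ~0.00) — see the coverage-estimand discussion above.
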