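# sterilecount

Mixed-model analysis of chemical-hybridizing-agent (CHA) sterility assays
in wheat crossing blocks.

## The problem

To produce hybrid wheat seed, female parents are sprayed with a CHA that
suppresses pollen formation; efficacy is assayed by bagging heads under
pollen-impermeable bags and counting the seeds that form by
self-pollination. A fully sterilized head sets 0 seeds; a healthy head sets
about 30. The resulting per-head seed counts are severely zero-inflated
(40–65% zeros), right-skewed, and unbalanced (bags are lost to wind) — data
that standard Gaussian or transformed-Gaussian analyses handle badly.
`sterilecount` is for plant breeders and biometricians who need to (a)
screen genotypes for adequate sterility and (b) estimate, per genotype, the
chance of complete sterilization and the expected seed count when
sterilization is incomplete.

## Models

All models share the linear predictor `eta_ijk = alpha_i + b_j + u_ij`
(genotype cell means, optional block and whole-plot normal random
intercepts on the link scale):

* **Threshold screening** — a head is a *success* if its count is at or
  below a sterility threshold (default 7 ≈ 75% sterility); logit/probit
  GLMMs fitted by adaptive Gauss–Hermite quadrature give genotype
  sterility proportions and a Type III genotype test.
* **Count ladder** — Gaussian (raw and `log(y+1)`, `sqrt(y+3/8)`,
  `y^(2/3)` transformed, REML), Poisson and NB2 GLMMs, and the two mixture
  models: zero-inflated NB, `Pr(0) = pi + (1-pi) f(0)`, and hurdle NB,
  `Pr(0) = pi` with zero-truncated NB positives, each with a single or
  per-genotype inflation probability `pi` on the logit scale. Marginal
  likelihoods use a joint Laplace approximation or adaptive Gauss–Hermite
  quadrature; model choice uses AICc/BIC and the Pearson chi-square/d.f.
  overdispersion ratio.
* **Coverage simulation** — simulate crossing-block experiments from a
  zero-inflated NB process and measure the empirical coverage of each
  model's nominal 95% genotype intervals, quantifying what using the wrong
  model costs.

A synthetic crossing-block generator (per-genotype `(pi, lambda)`, NB
dispersion `k`, blocks, subsampled heads, random bag loss) reproduces the
published study conditions for both trial years, so the whole pipeline is
testable without the field data. See `docs/methods.md` for assumptions,
parameterizations and numerical details.

## Worked example

```python
from sterilecount import (paper_like_config, generate_crossing_block, summarize,
                          ModelSpec, fit_family, ThresholdModel, ThresholdConfig,
                          type3_genotype_test, inflation_probabilities)

cfg = paper_like_config(2015, seed=1)      # published 2015 study conditions
data = generate_crossing_block(cfg)        # one synthetic crossing block
s = summarize(data)["2015"]
print(s.n_obs, round(s.mean, 2), round(s.prop_zero, 3))
# 370 5.52 0.416  -> ~371 heads, ~5.5 seeds/head, ~40% zeros, as designed

tfit = ThresholdModel(data, ThresholdConfig(7, "probit"),
                      estimation="ml_laplace").fit()
print(type3_genotype_test(tfit))
# (2.16, 0.0057)  -> genotypes differ in the frequency of >=75% sterility

fit = fit_family(data, ModelSpec(family="hnb", inflation="per_genotype",
                                 random_block=True))
means = {e.genotype: e for e in fit.genotype_means()}
e = means["TX12M4063"]
print(round(e.estimate, 2), (round(e.ci_low, 2), round(e.ci_high, 2)))
# 18.18 (12.2, 27.09) -> worst genotype: ~18 seeds/head when not sterile
pis = {e.genotype: e.pi for e in inflation_probabilities(fit)}
print(round(pis["TX12M4065"], 3))
# 0.105 -> this genotype is almost never completely sterilized
```

The genotype mean is the inverse-linked genotype effect (`exp(alpha_i)`,
the seed count of a non-sterilized head) with a Wald interval built on the
link scale; the inflation probability `pi` estimates the proportion of
heads fully sterilized beyond what the count distribution itself explains,
with a Wald test against the no-inflation null.

The same stages are available from a shell:

```
sterilecount simulate --year 2015 --seed 1 --out data.csv
sterilecount summarize --input data.csv
sterilecount threshold --input data.csv --threshold 7 --link probit --out results/
sterilecount count --input data.csv --family hnb --inflation per_genotype --out results/
sterilecount coverage --experiments 100 --seed 42 --out results/
```

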