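"""Empirical coverage study: simulate crossing-block experiments from a
zero-inflated NB process, fit the model ladder to each, and record whether
each model's nominal 95% interval for the genotype seed-count estimate
contains the generating value.

Coverage is a binary indicator per genotype per experiment (1 iff the true
value lies inside the interval, endpoints inclusive) averaged per model.
The generating value each interval is tested against is, by default, the
genotype count-mean parameter ``lambda_g`` that was set in the simulation;
``truth="data_scale_mean"`` instead tests against the process mean
``(1-pi_g) lambda_g``.  Each model contributes the interval for its own
genotype seed-count estimate: the back-transformed LS-mean for the
(transformed-)Gaussian rows, ``exp(alpha_g)`` for the log-link count rows
(for ZINB that is exactly the lambda parameter), and the model-implied
data-scale mean for the hurdle row, whose structural-zero probability is
misspecified under a zero-inflated process — the failure mode the study is
designed to expose.

Count-model intervals are symmetric data-scale Wald intervals (estimate
``+/- z * SE`` with the SE propagated to the data scale by the delta
method); transformed-Gaussian intervals are the back-transformed link-scale
bounds, with the delta-method-SE variant recorded alongside.

Whole-plot (subsampling) random effects are dropped from the fitted models
by default for computational efficiency; non-convergent fits are excluded
from the denominator, with the exclusion count reported.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .counts import (
    datascale_wald_intervals,
    delta_method_se,
    fit_family,
    genotype_count_means,
)
from .distributions import TransformSpec
from .generate import GeneratorConfig, generate_crossing_block
from .glmm import ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageConfig",
    "CoverageResult",
    "coverage_indicator",
    "run_coverage_study",
    "coverage_report",
    "default_model_ladder",
]


def default_model_ladder(inflation: str = "per_genotype"):
    """The eight-model ladder of the coverage study (no random effects by
    default: the simulated process is i.i.d. given the genotype)."""
    return [
        ModelSpec(family="gaussian", transform="identity"),
        ModelSpec(family="gaussian", transform="log_plus_one"),
        ModelSpec(family="gaussian", transform="sqrt_three_eighths"),
        ModelSpec(family="gaussian", transform="two_thirds_power"),
        ModelSpec(family="poisson"),
        ModelSpec(family="negbin"),
        ModelSpec(family="hnb", inflation=inflation),
        ModelSpec(family="zinb", inflation=inflation),
    ]


@dataclasses.dataclass
class CoverageConfig:
    """Configuration of one coverage study (see module docstring)."""

    generator: GeneratorConfig
    n_experiments: int
    models: list = dataclasses.field(default_factory=default_model_ladder)
    nominal_level: float = 0.95
    drop_subsampling: bool = True
    truth: str = "lambda"  # or "data_scale_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if not (0.0 < self.nominal_level < 1.0):
            raise ValueError("nominal_level must lie in (0, 1)")
        if self.truth not in ("lambda", "data_scale_mean"):
            raise ValueError(f"unknown truth convention {self.truth!r}")


@dataclasses.dataclass
class ModelCoverage:
    """Pooled coverage of one model across the simulated experiments."""

    model: str
    coverage: float
    sd_coverage: float  # SD of the binary indicator, sqrt(p(1-p))
    coverage_delta: float  # delta-method-SE interval variant (transformed rows)
    n_intervals: int
    n_excluded_fits: int
    mean_ci_width: float
    se_mc: float  # experiment-clustered Monte-Carlo SE of the coverage


@dataclasses.dataclass
class CoverageResult:
    """Per-model empirical coverage of nominal CIs across experiments."""

    per_model: list  # list of ModelCoverage, in config.models order
    n_experiments: int
    nominal_level: float
    truth: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(m) for m in self.per_model])

    def by_name(self) -> dict:
        return {m.model: m for m in self.per_model}


def coverage_indicator(ci_low: float, ci_high: float, true_value: float) -> int:
    """1 iff ``ci_low <= true_value <= ci_high`` (endpoints inclusive).

    Non-finite bounds count as non-coverage (the caller logs a flag).
    """
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        return 0
    if ci_low > ci_high:
        raise ValueError(f"ci_low {ci_low} > ci_high {ci_high}")
    return int(ci_low <= true_value <= ci_high)


def _intervals_for(fit, spec: ModelSpec, level: float):
    """(estimate, lo, hi) triples per genotype, plus the delta-SE variant."""
    from scipy import stats as sps

    z = sps.norm.ppf(0.5 + level / 2.0)
    if spec.family == "gaussian":
        ests = genotype_count_means(fit, level)
        tf = TransformSpec(spec.transform)
        alpha = fit.alpha().to_numpy()
        se = fit.bse[[f"alpha[{g}]" for g in fit.model.genotypes]].to_numpy()
        delta = []
        for e, a, s in zip(ests, alpha, se):
            d = delta_method_se(tf.inverse, max(a, 0.0) if tf.name == "two_thirds_power" else a, s)
            delta.append((e.estimate, e.estimate - z * d, e.estimate + z * d))
        return [(e.estimate, e.ci_low, e.ci_high) for e in ests], delta
    estimand = "marginal" if spec.family == "hnb" else "component"
    return datascale_wald_intervals(fit, level, estimand=estimand), None


def run_coverage_study(config: CoverageConfig) -> CoverageResult:
    """Run the study; fully reproducible from ``config.seed``."""
    gen = config.generator
    if config.truth == "lambda":
        truth = gen.true_lambda()
    else:
        truth = gen.true_data_scale_mean()
    genotypes = list(gen.genotype_labels)
    models = list(config.models)
    if config.drop_subsampling:
        models = [dataclasses.replace(m, name=m.name, random_wholeplot=False) for m in models]

    n_models = len(models)
    hits = [[] for _ in range(n_models)]         # per-experiment mean coverage
    flat = [[] for _ in range(n_models)]         # pooled indicators
    hits_delta = [[] for _ in range(n_models)]
    widths = [[] for _ in range(n_models)]
    excluded = [0] * n_models

    children = np.random.SeedSequence(config.seed).spawn(config.n_experiments)
    for e in range(config.n_experiments):
        child_seed = int(children[e].generate_state(1)[0] % (2**31))
        data = generate_crossing_block(dataclasses.replace(gen, seed=child_seed))
        present = set(data.df["genotype"].astype(str))
        for im, spec in enumerate(models):
            try:
                fit = fit_family(data, spec)
            except Exception as err:  # defensive: a failed fit is an exclusion
                logger.warning("experiment %d, model %s: %s", e, spec.name, err)
                excluded[im] += 1
                continue
            if not fit.converged:
                excluded[im] += 1
                continue
            try:
                triples, delta = _intervals_for(fit, spec, config.nominal_level)
            except ValueError:
                excluded[im] += 1
                continue
            fit_genotypes = fit.model.genotypes
            ind = []
            for g, (est, lo, hi) in zip(fit_genotypes, triples):
                if g not in present or g not in truth:
                    continue
                if not (np.isfinite(lo) and np.isfinite(hi)):
                    ind.append(0)
                    continue
                ind.append(coverage_indicator(min(lo, hi), max(lo, hi), truth[g]))
                widths[im].append(hi - lo)
            if ind:
                hits[im].append(float(np.mean(ind)))
                flat[im].extend(ind)
            if delta is not None:
                dind = [
                    coverage_indicator(min(lo, hi), max(lo, hi), truth[g])
                    if np.isfinite(lo) and np.isfinite(hi)
                    else 0
                    for g, (_, lo, hi) in zip(fit_genotypes, delta)
                    if g in present and g in truth
                ]
                hits_delta[im].extend(dind)

    per_model = []
    for im, spec in enumerate(models):
        n_int = len(flat[im])
        if n_int == 0:
            per_model.append(
                ModelCoverage(spec.name, float("nan"), float("nan"), float("nan"),
                              0, excluded[im], float("nan"), float("nan"))
            )
            continue
        cov = float(np.mean(flat[im]))
        sd = math.sqrt(cov * (1.0 - cov))
        cov_delta = float(np.mean(hits_delta[im])) if hits_delta[im] else float("nan")
        n_exp = len(hits[im])
        se_mc = (
            float(np.std(hits[im], ddof=1) / math.sqrt(n_exp)) if n_exp > 1 else float("nan")
        )
        per_model.append(
            ModelCoverage(
                model=spec.name,
                coverage=cov,
                sd_coverage=sd,
                coverage_delta=cov_delta,
                n_intervals=n_int,
                n_excluded_fits=excluded[im],
                mean_ci_width=float(np.mean(widths[im])) if widths[im] else float("nan"),
                se_mc=se_mc,
            )
        )
    return CoverageResult(
        per_model=per_model,
        n_experiments=config.n_experiments,
        nominal_level=config.nominal_level,
        truth=config.truth,
        seed=config.seed,
    )


def coverage_report(result: CoverageResult) -> pd.DataFrame:
    """One row per model: coverage and its indicator SD (plus diagnostics).

    Duplicated model specs yield duplicated rows; an empty model list yields
    a header-only table.
    """
    cols = [
        "model", "coverage", "sd_coverage", "coverage_delta",
        "n_intervals", "n_excluded_fits", "mean_ci_width", "se_mc",
    ]
    if not result.per_model:
        return pd.DataFrame(columns=cols)
    return result.to_frame()[cols]
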