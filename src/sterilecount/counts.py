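"""Count-model ladder: Gaussian/transformed, Poisson, NB, ZINB and HNB fits,
genotype seed-count estimates, inflation probabilities, and model comparison.

The data-scale genotype estimate of a count model is the inverse link of its
genotype linear predictor: ``exp(alpha_i)`` for the log-link families (for a
mixture family this is the count-component mean, the lambda parameter), and
the naive back-transform of the LS-mean for the transformed-Gaussian
families.  Naive back-transformation deliberately mirrors the conventional
practice whose failure modes (nonsensical negative counts, understated
uncertainty) the coverage study quantifies: estimates or interval endpoints
below zero are flagged, not corrected.  ``marginal_genotype_means`` instead
reports each model's implied data-scale mean of the observations (for a
hurdle model ``(1-pi) * lambda / (1 - f(0))``), with delta-method intervals.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .distributions import TransformSpec
from .glmm import (
    COUNT_FAMILIES,
    MIXTURE_FAMILIES,
    FitResult,
    ModelSpec,
    SterilityModel,
    _numdiff_grad,
    pearson_overdispersion,
)
from .threshold import GenotypeEstimate

__all__ = [
    "InflationEstimate",
    "ModelComparison",
    "fit_family",
    "genotype_count_means",
    "marginal_genotype_means",
    "inflation_probabilities",
    "delta_method_se",
    "compare_models",
]


@dataclasses.dataclass
class InflationEstimate:
    """An inflation-probability estimate with 95% CI and a pi=0 Wald test."""

    genotype: str  # a genotype label, or "overall" for a single-pi fit
    pi: float
    ci_low: float
    ci_high: float
    p_value: float
    flags: list = dataclasses.field(default_factory=list)


def fit_family(data, spec: ModelSpec, **kwargs) -> FitResult:
    """Fit one row of the model ladder (transformed-Gaussian rows transform
    the response and use REML; count rows use marginal ML)."""
    return SterilityModel(data, spec).fit(**kwargs)


def _check_count_fit(fit: FitResult) -> None:
    if fit.spec.family == "gaussian":
        return
    if fit.spec.family not in COUNT_FAMILIES:
        raise ValueError("genotype count means require a count or gaussian family fit")


def genotype_count_means(fit: FitResult, level: float = 0.95):
    """Data-scale genotype seed-count estimates with Wald CIs.

    For log-link families the estimate is exactly ``exp(alpha_i)`` with the
    interval inverse-linked from the link scale; for (transformed) Gaussian
    fits, the naive back-transform of the LS-mean and its interval.  Negative
    back-transformed values are flagged ``nonsensical_negative_count``.
    """
    _check_count_fit(fit)
    if not fit.converged:
        raise ValueError("refusing to summarize a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    alpha = fit.alpha().to_numpy()
    se = fit.bse[[f"alpha[{g}]" for g in fit.model.genotypes]].to_numpy()
    out = []
    tf = TransformSpec(fit.spec.transform)
    for g, a, s in zip(fit.model.genotypes, alpha, se):
        flags = []
        if f"alpha[{g}]" in fit.flags["non_estimable"]:
            flags.append("non_estimable")
        if fit.spec.family == "gaussian":
            lo_link, hi_link = a - z * s, a + z * s
            if tf.name == "two_thirds_power":
                if lo_link < 0:
                    flags.append("nonsensical_negative_count")
                lo_link, hi_link = max(lo_link, 0.0), max(hi_link, 0.0)
                a_ = max(a, 0.0)
            else:
                a_ = a
            est = float(tf.inverse(np.asarray(a_)))
            lo = float(tf.inverse(np.asarray(lo_link)))
            hi = float(tf.inverse(np.asarray(hi_link)))
        else:
            est, lo, hi = math.exp(a), math.exp(a - z * s), math.exp(a + z * s)
        if est < 0 or lo < 0:
            if "nonsensical_negative_count" not in flags:
                flags.append("nonsensical_negative_count")
        out.append(GenotypeEstimate(g, est, lo, hi, scale="count", flags=flags))
    return out


def _log_marginal_means(model: SterilityModel, theta: np.ndarray) -> np.ndarray:
    """log of the model-implied data-scale mean per genotype at ``theta``."""
    u = model._unpack(theta)
    alpha = u["alpha"]
    fam = model.spec.family
    if fam == "gaussian":
        raise ValueError("use genotype_count_means for gaussian fits")
    if fam in ("poisson", "negbin"):
        return alpha.copy()
    k = u["k"]
    if model.spec.inflation == "single":
        pi = np.full(model.n_genotypes, u["pi_obs"][0])
    else:
        pi = u["pi_by_g"]
    if fam == "zinb":
        return np.log1p(-pi) + alpha
    # hurdle: (1-pi) * lam / (1 - f(0))
    lam = np.exp(alpha)
    log_f0 = k * (np.log(k) - np.log(k + lam))
    return np.log1p(-pi) + alpha - np.log1p(-np.exp(log_f0))


def marginal_genotype_means(fit: FitResult, level: float = 0.95):
    """Model-implied data-scale mean seed count per genotype with delta CIs.

    The interval is symmetric on the log scale: ``m * exp(±z * se_log m)``
    with the delta-method SE propagated through the full parameter
    covariance (numeric Jacobian).
    """
    _check_count_fit(fit)
    if fit.spec.family == "gaussian":
        return genotype_count_means(fit, level)
    if not fit.converged:
        raise ValueError("refusing to summarize a non-converged fit")
    model = fit.model
    theta = fit.params.to_numpy()
    G = model.n_genotypes
    logm = _log_marginal_means(model, theta)
    # numeric Jacobian of the log means (p x G)
    p = theta.size
    J = np.empty((G, p))
    for i in range(p):
        h = 1e-6 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (_log_marginal_means(model, tp) - _log_marginal_means(model, tm)) / (2 * h)
    V = fit.cov_params.to_numpy()
    se_log = np.sqrt(np.clip(np.einsum("gp,pq,gq->g", J, V, J), 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for g, lm, s in zip(model.genotypes, logm, se_log):
        flags = []
        if f"alpha[{g}]" in fit.flags["non_estimable"]:
            flags.append("non_estimable")
        out.append(
            GenotypeEstimate(
                g, math.exp(lm), math.exp(lm - z * s), math.exp(lm + z * s),
                scale="count", flags=flags,
            )
        )
    return out


def datascale_wald_intervals(fit: FitResult, level: float = 0.95, estimand: str = "component"):
    """Symmetric data-scale Wald intervals ``m +/- z * se(m)`` per genotype.

    ``estimand="component"`` uses the inverse-linked genotype linear
    predictor (``exp(alpha_g)``; the count-component mean for mixtures);
    ``estimand="marginal"`` uses the model-implied data-scale mean.  The SE
    is first-order (delta method) from the full parameter covariance.
    Returns a list of ``(estimate, ci_low, ci_high)`` triples in genotype
    order.  This is the interval construction of the coverage study; the
    genotype tables use link-scale (asymmetric) intervals instead.
    """
    _check_count_fit(fit)
    if fit.spec.family == "gaussian":
        raise ValueError("data-scale Wald intervals are for count-family fits")
    z = stats.norm.ppf(0.5 + level / 2.0)
    model = fit.model
    theta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    if estimand == "component":
        alpha = fit.alpha().to_numpy()
        se_log = fit.bse[[f"alpha[{g}]" for g in model.genotypes]].to_numpy()
        logm = alpha
    elif estimand == "marginal":
        logm = _log_marginal_means(model, theta)
        G, p = model.n_genotypes, theta.size
        J = np.empty((G, p))
        for i in range(p):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            J[:, i] = (
                _log_marginal_means(model, tp) - _log_marginal_means(model, tm)
            ) / (2 * h)
        se_log = np.sqrt(np.clip(np.einsum("gp,pq,gq->g", J, V, J), 0.0, None))
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    m = np.exp(logm)
    se_m = m * se_log  # delta method through exp
    return [(float(mm), float(mm - z * ss), float(mm + z * ss)) for mm, ss in zip(m, se_m)]


def inflation_probabilities(fit: FitResult, level: float = 0.95):
    """Inverse-logit inflation probabilities with Wald CIs.

    Each estimate carries a Wald test against the no-zero-inflation null
    (pi = 0), computed with the delta-method SE on the probability scale.
    A single-pi fit returns one estimate labeled ``"overall"``.
    """
    if fit.spec.family not in MIXTURE_FAMILIES:
        raise ValueError("inflation probabilities require a zinb or hnb fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if fit.spec.inflation == "single":
        labels, names = ["overall"], ["logit_pi"]
    else:
        labels = list(fit.model.genotypes)
        names = [f"logit_pi[{g}]" for g in labels]
    out = []
    for label, name in zip(labels, names):
        gamma = float(fit.params[name])
        se = float(fit.bse[name])
        pi = float(special.expit(gamma))
        lo = float(special.expit(gamma - z * se))
        hi = float(special.expit(gamma + z * se))
        se_prob = pi * (1.0 - pi) * se
        zstat = pi / se_prob if se_prob > 0 else math.inf
        pval = 2.0 * float(stats.norm.sf(abs(zstat)))
        flags = []
        if name in fit.flags["non_estimable"]:
            flags.append("non_estimable")
        if lo <= 1e-6:
            flags.append("boundary_zero")
        out.append(InflationEstimate(label, pi, lo, hi, pval, flags))
    return out


def delta_method_se(transform_inverse, x: float, se_x: float, step: float = 1e-6) -> float:
    """First-order (delta-method) SE of ``g(x)``: ``|g'(x)| * se_x``.

    The derivative is taken numerically (central difference); a zero
    derivative returns an SE of exactly 0.
    """
    h = step * max(1.0, abs(x))
    d = (float(transform_inverse(x + h)) - float(transform_inverse(x - h))) / (2 * h)
    return abs(d) * se_x


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

_GROUPS = {
    "gaussian": "transformed-gaussian",
    "poisson": "count",
    "negbin": "count",
    "zinb": "count",
    "hnb": "count",
    "binary_logit": "binary",
    "binary_probit": "binary",
}


@dataclasses.dataclass
class ModelComparison:
    """Fit-statistic table across a ladder of models.

    Fit statistics are only directly rankable within a likelihood-comparable
    group; transformed-scale rows carry a different response and are marked
    not comparable to the count-likelihood rows.
    """

    table: pd.DataFrame
    fits: list

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_models(data, specs, **fit_kwargs) -> ModelComparison:
    """Fit every spec and tabulate AICc/BIC/-2LL (sorted by AICc in-group).

    Non-converged rows are retained with ``converged=False``; Pearson
    chi-square/d.f. is reported for count families.
    """
    if len(specs) < 2:
        raise ValueError("model comparison needs at least 2 specs")
    rows, fits = [], []
    for spec in specs:
        fit = fit_family(data, spec, **fit_kwargs)
        fits.append(fit)
        chi2 = np.nan
        if spec.family in COUNT_FAMILIES and fit.converged:
            chi2 = pearson_overdispersion(fit)
        rows.append(
            {
                "model": spec.name,
                "family": spec.family,
                "group": _GROUPS[spec.family],
                "comparable": _GROUPS[spec.family] == "count",
                "AICc": fit.aicc,
                "BIC": fit.bic,
                "minus2LL": fit.minus2ll,
                "chi2_df": chi2,
                "n_params": fit.n_params,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(["group", "AICc"], kind="stable").reset_index(drop=True)
    return ModelComparison(table=table, fits=fits)


def means_table(estimates) -> pd.DataFrame:
    """Genotype estimates as a table (CLI output helper)."""
    return pd.DataFrame(
        [dataclasses.asdict(e) | {"flags": ";".join(e.flags)} for e in estimates]
    )
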