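"""Binary threshold analysis of sterility: logit/probit GLMMs.

A bagged head is scored a *success* when its seed count is at or below a
sterility threshold (default 7 seeds, i.e. roughly 75% sterility against the
~30 seeds of a healthy Great Plains winter-wheat head).  The success
indicator is modelled by a binomial GLMM with genotype fixed effects and
block + whole-plot random intercepts, fitted by adaptive Gauss-Hermite
quadrature by default.  Genotype sterility proportions are inverse-link
estimates with Wald intervals built on the link scale; the joint genotype
effect is tested with a Wald-type Type III F statistic.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SeedCountDataset
from .distributions import link as get_link
from .glmm import FitResult, ModelSpec, SterilityModel

__all__ = [
    "ThresholdConfig",
    "GenotypeEstimate",
    "binarize",
    "ThresholdModel",
    "fit_threshold",
    "genotype_proportions",
    "type3_genotype_test",
]


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    """Sterility cutoff and link for the binary analysis.

    ``threshold`` is a configuration value, not a constant: 7 corresponds to
    ~75% sterility for a typical 30-seed head, the working acceptance level
    for experimental hybrid seed production.
    """

    threshold: int = 7
    link: str = "probit"

    def __post_init__(self) -> None:
        t = self.threshold
        if not np.isfinite(t):
            raise ValueError(
                "threshold must be finite: an infinite threshold makes every head "
                "a success and the binary model degenerate"
            )
        if t < 0 or t != int(t):
            raise ValueError(f"threshold must be a nonnegative integer, got {t}")
        if self.link not in ("logit", "probit"):
            raise ValueError(f"link must be 'logit' or 'probit', got {self.link!r}")


@dataclasses.dataclass
class GenotypeEstimate:
    """A data-scale genotype estimate (proportion or mean count) with 95% CI."""

    genotype: str
    estimate: float
    ci_low: float
    ci_high: float
    scale: str  # "proportion" or "count"
    flags: list = dataclasses.field(default_factory=list)


def binarize(data: SeedCountDataset, config: ThresholdConfig) -> SeedCountDataset:
    """Add a 0/1 ``success`` column: 1 iff ``seed_count <= threshold``."""
    df = data.df.copy()
    df["success"] = (df["seed_count"] <= config.threshold).astype("int64")
    return SeedCountDataset(df, {**data.metadata, "threshold": config.threshold})


class ThresholdModel(SterilityModel):
    """Binary threshold GLMM bound to one dataset (see module docstring)."""

    def __init__(
        self,
        data,
        config: ThresholdConfig | None = None,
        random_block: bool = True,
        random_wholeplot: bool = True,
        estimation: str = "ml_agq",
        agq_nodes: int = 9,
    ):
        config = config or ThresholdConfig()
        self.config = config
        data = data if isinstance(data, SeedCountDataset) else SeedCountDataset(pd.DataFrame(data))
        binar = binarize(data, config)
        spec = ModelSpec(
            family="binary_logit" if config.link == "logit" else "binary_probit",
            random_block=random_block,
            random_wholeplot=random_wholeplot,
            estimation=estimation,
            agq_nodes=agq_nodes,
        )
        super().__init__(binar, spec, response_col="success")


def fit_threshold(data, config: ThresholdConfig | None = None, **kwargs) -> FitResult:
    """Fit the binary threshold GLMM; returns a :class:`FitResult`."""
    return ThresholdModel(data, config, **kwargs).fit()


def _link_name(fit: FitResult) -> str:
    return "logit" if fit.spec.family == "binary_logit" else "probit"


def genotype_proportions(fit: FitResult, level: float = 0.95):
    """Inverse-link genotype sterility proportions with Wald CIs.

    The interval is built on the link scale and inverse-linked, then clipped
    to [0, 1]; boundary estimates (complete separation) are flagged rather
    than corrected.
    """
    if fit.spec.family not in ("binary_logit", "binary_probit"):
        raise ValueError("genotype_proportions requires a threshold-model fit")
    if not fit.converged:
        raise ValueError("refusing to summarize a non-converged fit")
    inv = get_link(_link_name(fit))[1]
    z = stats.norm.ppf(0.5 + level / 2.0)
    alpha = fit.alpha()
    se = fit.bse[[f"alpha[{g}]" for g in fit.model.genotypes]].to_numpy()
    out = []
    for g, a, s in zip(fit.model.genotypes, alpha.to_numpy(), se):
        est = float(inv(a))
        lo = float(inv(a - z * s))
        hi = float(inv(a + z * s))
        flags = []
        if f"alpha[{g}]" in fit.flags["non_estimable"]:
            flags.append("boundary")
            lo, hi = max(0.0, min(lo, est)), min(1.0, max(hi, est))
        out.append(
            GenotypeEstimate(
                genotype=g,
                estimate=min(max(est, 0.0), 1.0),
                ci_low=min(max(lo, 0.0), 1.0),
                ci_high=min(max(hi, 0.0), 1.0),
                scale="proportion",
                flags=flags,
            )
        )
    return out


def type3_genotype_test(fit: FitResult):
    """Wald-type Type III F test of equal genotype effects.

    The contrast matrix compares every genotype to the last; the F statistic
    is ``(L theta)' (L V L')^{-1} (L theta) / (G - 1)``.  Denominator degrees
    of freedom follow a containment-style rule: ``(G-1)(J-1)`` when the
    whole-plot (genotype-by-block) random effect is in the model, otherwise
    the residual ``n - G``.  Returns ``(F, p)``.
    """
    G = fit.model.n_genotypes
    if G < 2:
        raise ValueError("Type III genotype test needs at least 2 genotypes")
    names = [f"alpha[{g}]" for g in fit.model.genotypes]
    theta = fit.params[names].to_numpy()
    V = fit.cov_params.loc[names, names].to_numpy()
    L = np.hstack([np.eye(G - 1), -np.ones((G - 1, 1))])
    Lt = L @ theta
    M = L @ V @ L.T
    try:
        sol = np.linalg.solve(M, Lt)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular genotype contrast covariance; test not computable"
        ) from err
    F = float(Lt @ sol) / (G - 1)
    J = len(fit.model.blocks)
    if fit.spec.random_wholeplot and J > 1:
        ddf = (G - 1) * (J - 1)
    else:
        ddf = max(fit.n_obs - G, 1)
    p = float(stats.f.sf(F, G - 1, ddf))
    return F, p


def proportions_table(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Genotype proportions as a table (CLI output helper)."""
    rows = [
        dataclasses.asdict(e) | {"flags": ";".join(e.flags)}
        for e in genotype_proportions(fit, level)
    ]
    return pd.DataFrame(rows)
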