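"""Probability mass functions, link functions, and response transformations.

The two mixture families at the core of the sterility analysis share a base
count distribution ``f`` (Poisson or NB2 negative binomial with mean ``lam``
and dispersion ``k``, variance ``lam + lam**2/k``):

* zero-inflated:  Pr(0) = pi + (1-pi) f(0),   Pr(y>=1) = (1-pi) f(y)
* hurdle:         Pr(0) = pi,                 Pr(y>=1) = (1-pi) f(y) / (1 - f(0))

``pi`` is the inflation probability: the mixture weight of the structural-zero
state (a head fully sterilized by the hybridizing agent).  All log-PMFs are
evaluated in numerically stable form (log-sum-exp for the zero-inflated zero
cell, ``log1p`` for the hurdle normalization).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import special, stats

__all__ = [
    "MixturePMFParams",
    "TransformSpec",
    "base_pmf",
    "base_log_pmf",
    "mixture_pmf",
    "mixture_log_pmf",
    "transform",
    "inverse_transform",
    "link",
    "TRANSFORMS",
    "LINKS",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MixturePMFParams:
    """Parameters of a zero-inflated or hurdle count distribution.

    Parameters
    ----------
    pi : float
        Inflation probability (mixture weight of the structural zero), in [0, 1].
    lam : float
        Mean of the base count distribution, > 0.
    k : float
        NB2 dispersion (variance ``lam + lam**2/k``); ``math.inf`` gives the
        Poisson limit.
    base : {"negbin", "poisson"}
    kind : {"zero_inflated", "hurdle"}
    """

    pi: float
    lam: float
    k: float = math.inf
    base: str = "negbin"
    kind: str = "zero_inflated"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")
        if not (self.lam > 0.0 and np.isfinite(self.lam)):
            raise ValueError(f"lam must be a positive finite real, got {self.lam}")
        if not self.k > 0.0:
            raise ValueError(f"k must be positive (may be inf), got {self.k}")
        if self.base not in ("poisson", "negbin"):
            raise ValueError(f"unknown base distribution {self.base!r}")
        if self.kind not in ("zero_inflated", "hurdle"):
            raise ValueError(f"unknown mixture kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class TransformSpec:
    """A named variance-stabilizing response transformation.

    ``log_plus_one``      log(y + 1)
    ``sqrt_three_eighths`` sqrt(y + 3/8)
    ``two_thirds_power``  y**(2/3)
    ``identity``          y
    """

    name: str = "identity"

    def __post_init__(self) -> None:
        if self.name not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.name!r}; known: {sorted(TRANSFORMS)}"
            )

    @property
    def forward(self):
        return TRANSFORMS[self.name][0]

    @property
    def inverse(self):
        return TRANSFORMS[self.name][1]


# ---------------------------------------------------------------------------
# base count distributions
# ---------------------------------------------------------------------------

def base_log_pmf(y, lam, k=math.inf):
    """Log-PMF of the base count distribution: NB2(lam, k) or Poisson(lam).

    NB2 log-pmf: ``lgamma(y+k) - lgamma(k) - lgamma(y+1)
    + k*log(k/(k+lam)) + y*log(lam/(k+lam))``.  ``k = inf`` selects Poisson.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be nonnegative integers")
    if not np.all(np.asarray(lam) > 0):
        raise ValueError("lam must be positive")
    if np.isinf(k):
        return y * np.log(lam) - lam - special.gammaln(y + 1.0)
    if not k > 0:
        raise ValueError("k must be positive")
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * (np.log(k) - np.log(k + lam))
        + y * (np.log(lam) - np.log(k + lam))
    )


def base_pmf(y, lam, k=math.inf):
    """PMF of the base count distribution (see :func:`base_log_pmf`)."""
    return np.exp(base_log_pmf(y, lam, k))


def mixture_log_pmf(y, params: MixturePMFParams):
    """Stable log-PMF of the zero-inflated or hurdle mixture."""
    y = np.asarray(y)
    base0 = base_log_pmf(0, params.lam, params.k)  # log f(0)
    basey = base_log_pmf(np.maximum(y, 0), params.lam, params.k)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi) if params.pi > 0 else -np.inf
        log_1mpi = np.log1p(-params.pi) if params.pi < 1 else -np.inf
    if params.kind == "zero_inflated":
        zero_cell = np.logaddexp(log_pi, log_1mpi + base0)
        pos_cell = log_1mpi + basey
    else:  # hurdle
        if base0 >= 0.0:  # f(0) == 1: zero-truncation undefined
            raise ZeroDivisionError(
                "hurdle mixture degenerate: base distribution has f(0) = 1"
            )
        zero_cell = log_pi
        pos_cell = log_1mpi + basey - np.log1p(-np.exp(base0))
    return np.where(y == 0, zero_cell, pos_cell)


def mixture_pmf(y, params: MixturePMFParams):
    """PMF of the zero-inflated or hurdle mixture.

    The hurdle zero cell is exactly ``pi`` (returned without passing through
    log space, so the structural identity holds bit-for-bit).
    """
    out = np.exp(mixture_log_pmf(y, params))
    if params.kind == "hurdle":
        out = np.where(np.asarray(y) == 0, params.pi, out)
    return out[()] if np.ndim(y) == 0 else out


# ---------------------------------------------------------------------------
# response transformations
# ---------------------------------------------------------------------------

def _log1p_fwd(y):
    return np.log1p(y)


def _log1p_inv(x):
    return np.expm1(x)


def _sqrt38_fwd(y):
    return np.sqrt(np.asarray(y, dtype=float) + 0.375)


def _sqrt38_inv(x):
    return np.square(x) - 0.375


def _pow23_fwd(y):
    return np.power(np.asarray(y, dtype=float), 2.0 / 3.0)


def _pow23_inv(x):
    return np.power(np.asarray(x, dtype=float), 1.5)


TRANSFORMS = {
    "identity": (lambda y: np.asarray(y, dtype=float), lambda x: np.asarray(x, dtype=float)),
    "log_plus_one": (_log1p_fwd, _log1p_inv),
    "sqrt_three_eighths": (_sqrt38_fwd, _sqrt38_inv),
    "two_thirds_power": (_pow23_fwd, _pow23_inv),
}


def transform(y, spec: TransformSpec):
    """Forward response transformation; counts must be nonnegative."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("transforms are defined for nonnegative counts")
    return spec.forward(y)


def inverse_transform(x, spec: TransformSpec):
    """Back-transform to the data (count) scale.

    The result can be negative (e.g. ``expm1`` of a negative linear-predictor
    bound): callers are expected to flag such values as nonsensical counts
    rather than have this function mask them.
    """
    x = np.asarray(x, dtype=float)
    if spec.name == "two_thirds_power" and np.any(x < 0):
        raise ValueError("two_thirds_power inverse undefined for negative values")
    return spec.inverse(x)


# ---------------------------------------------------------------------------
# link functions
# ---------------------------------------------------------------------------

def _logit(p):
    p = np.asarray(p, dtype=float)
    return special.logit(p)


LINKS = {
    "logit": (_logit, special.expit),
    "probit": (stats.norm.ppf, special.ndtr),
    "log": (np.log, np.exp),
    "identity": (lambda x: np.asarray(x, dtype=float), lambda x: np.asarray(x, dtype=float)),
}


def link(name: str):
    """Return the ``(forward, inverse)`` pair for a named link function."""
    try:
        return LINKS[name]
    except KeyError:
        raise ValueError(f"unknown link {name!r}; known: {sorted(LINKS)}") from None
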