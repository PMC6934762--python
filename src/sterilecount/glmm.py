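"""Marginal maximum-likelihood machinery for the sterility mixed models.

The linear predictor for genotype i in block j is

    eta_ijk = alpha_i + b_j + u_ij

with cell-means genotype coding (one fixed effect per genotype on the link
scale) and i.i.d. normal random effects ``b_j ~ N(0, sigma_b^2)`` (block) and
``u_ij ~ N(0, sigma_ab^2)`` (whole plot = genotype-by-block experimental
unit, above the bagged-head sampling level).  Random effects enter the log
mean of the count process (shared by both mixture components) or the binary
linear predictor.

Families: ``gaussian`` (optionally on a transformed response, fitted by
REML in closed form over the marginal covariance), ``poisson``, ``negbin``
(NB2), ``zinb``, ``hnb`` (zero-inflated / hurdle NB with a single or
per-genotype inflation probability on the logit scale) and ``binary_logit`` /
``binary_probit`` for the threshold analysis.

Random effects are integrated out by a joint Laplace approximation
(mode-finding per block with the exact arrow-structured Hessian) or by
adaptive Gauss-Hermite quadrature (one level directly; two nested levels by
adaptive quadrature of the whole-plot integrals inside the block integral).
With a variance component at (numerical) zero the corresponding integral
collapses exactly to the conditional sum.

The optimizer works on a transformed space (log variance components, log NB
dispersion, logit inflation probabilities) with bounded quasi-Newton steps
and finite-difference gradients; mixture families get deterministic restart
perturbations.  Non-convergence is reported in the :class:`FitResult`, never
raised.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import log_ndtr, logsumexp

from .datasets import SeedCountDataset
from .distributions import TransformSpec, link

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "SterilityModel",
    "FitResult",
    "marginal_loglik",
    "fit",
    "information_criteria",
    "pearson_overdispersion",
]

COUNT_FAMILIES = ("poisson", "negbin", "zinb", "hnb")
MIXTURE_FAMILIES = ("zinb", "hnb")
BINARY_FAMILIES = ("binary_logit", "binary_probit")
FAMILIES = ("gaussian",) + COUNT_FAMILIES + BINARY_FAMILIES

_SIGMA_ZERO2 = 1e-12  # variance below this is treated as exactly zero
_LOG_SIGMA_BOUNDS = (-6.0, 2.5)
_LOGIT_PI_BOUNDS = (-12.0, 12.0)
_LOG_K_BOUNDS = (-6.0, 9.0)
_ALPHA_BOUNDS = (-15.0, 15.0)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model in the analysis ladder.

    Parameters
    ----------
    family : str
        One of ``gaussian, poisson, negbin, zinb, hnb, binary_logit,
        binary_probit``.
    transform : str
        Response transformation (gaussian family only): ``identity``,
        ``log_plus_one``, ``sqrt_three_eighths`` or ``two_thirds_power``.
    inflation : {"none", "single", "per_genotype"}
        Structure of the inflation probability; required (and only allowed)
        for the ``zinb`` and ``hnb`` families.
    random_block, random_wholeplot : bool
        Include the block / whole-plot normal random intercepts.
    estimation : {"reml", "ml_laplace", "ml_agq"} or None
        Defaults to ``reml`` for gaussian and ``ml_laplace`` otherwise.
    agq_nodes : int
        Quadrature nodes per dimension for ``ml_agq``.
    """

    family: str
    transform: str = "identity"
    inflation: str = "none"
    random_block: bool = False
    random_wholeplot: bool = False
    estimation: str | None = None
    agq_nodes: int = 9
    name: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.inflation not in ("none", "single", "per_genotype"):
            raise ValueError(f"unknown inflation structure {self.inflation!r}")
        if (self.inflation != "none") != (self.family in MIXTURE_FAMILIES):
            raise ValueError(
                "inflation structure must be 'single' or 'per_genotype' for "
                "zinb/hnb and 'none' otherwise"
            )
        if self.transform != "identity" and self.family != "gaussian":
            raise ValueError("response transformations apply to the gaussian family only")
        TransformSpec(self.transform)  # validate name
        est = self.estimation
        if est is None:
            est = "reml" if self.family == "gaussian" else "ml_laplace"
            object.__setattr__(self, "estimation", est)
        if est not in ("reml", "ml_laplace", "ml_agq"):
            raise ValueError(f"unknown estimation method {est!r}")
        if (est == "reml") != (self.family == "gaussian"):
            raise ValueError("REML is for the gaussian family; ML for the others")
        if self.agq_nodes < 1:
            raise ValueError("agq_nodes must be positive")
        if self.name is None:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        if self.family == "gaussian":
            tags = {
                "identity": "gaussian",
                "log_plus_one": "log-transformed",
                "sqrt_three_eighths": "sqrt-transformed",
                "two_thirds_power": "two-thirds-transformed",
            }
            return tags[self.transform]
        if self.family in MIXTURE_FAMILIES:
            return f"{self.family}_{self.inflation}"
        return self.family


# ---------------------------------------------------------------------------
# conditional log-likelihood and its eta-derivatives, per family
# ---------------------------------------------------------------------------

def _nb_ll(y, mu, k):
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * (np.log(k) - np.log(k + mu))
        + y * (np.log(mu) - np.log(k + mu))
    )


def _cond_terms(family, y, eta, k=None, pi=None):
    """Per-observation conditional loglik and first/second eta-derivatives.

    ``pi`` is a per-observation inflation probability for mixture families.
    Derivatives are with respect to the linear predictor, which is all the
    Laplace/AGQ machinery needs because random effects enter only there.
    """
    if family == "poisson":
        mu = np.exp(eta)
        ll = y * eta - mu - special.gammaln(y + 1.0)
        return ll, y - mu, -mu
    if family == "negbin":
        mu = np.exp(eta)
        ll = _nb_ll(y, mu, k)
        d1 = k * (y - mu) / (k + mu)
        d2 = -k * mu * (k + y) / (k + mu) ** 2
        return ll, d1, d2
    if family == "binary_logit":
        p = special.expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        return ll, y - p, -p * (1.0 - p)
    if family == "binary_probit":
        q = 2.0 * y - 1.0
        z = q * eta
        logcdf = log_ndtr(z)
        r = np.exp(-0.5 * z * z - 0.5 * math.log(2 * math.pi) - logcdf)  # phi/Phi
        d1 = q * r
        d2 = -r * (z + r)
        return logcdf, d1, d2
    if family in MIXTURE_FAMILIES:
        mu = np.exp(eta)
        t = k * (np.log(k) - np.log(k + mu))  # log f(0)
        dt = -k * mu / (k + mu)
        d2t = -(k**2) * mu / (k + mu) ** 2
        with np.errstate(divide="ignore"):
            log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
            log_1mpi = np.where(pi < 1, np.log1p(-np.minimum(pi, 1 - 1e-16)), -np.inf)
        is_zero = y == 0
        nb = _nb_ll(y, mu, k)
        nb_d1 = k * (y - mu) / (k + mu)
        nb_d2 = -k * mu * (k + y) / (k + mu) ** 2
        if family == "zinb":
            l0 = np.logaddexp(log_pi, log_1mpi + t)
            w = np.exp(log_1mpi + t - l0)  # posterior weight of the NB branch at y=0
            ll = np.where(is_zero, l0, log_1mpi + nb)
            d1 = np.where(is_zero, w * dt, nb_d1)
            d2 = np.where(is_zero, w * (1.0 - w) * dt**2 + w * d2t, nb_d2)
            return ll, d1, d2
        # hurdle: zero cell is exactly pi; positives are zero-truncated NB
        f0 = np.exp(t)
        om = -np.log1p(-np.minimum(f0, 1 - 1e-12))  # -log(1 - f(0))
        c = f0 / np.maximum(1.0 - f0, 1e-12)
        ll = np.where(is_zero, log_pi, log_1mpi + nb + om)
        d1 = np.where(is_zero, 0.0, nb_d1 + c * dt)
        d2 = np.where(is_zero, 0.0, nb_d2 + c * (1.0 + c) * dt**2 + c * d2t)
        return ll, d1, d2
    raise ValueError(f"no conditional likelihood for family {family!r}")


# ---------------------------------------------------------------------------
# numerical differentiation helpers (numdifftools-free)
# ---------------------------------------------------------------------------

def _numdiff_grad(f, x, step=1e-5):
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g

def _numdiff_hessian(f, x, step=1e-4):
    """Central-difference Hessian; O(2 p^2 + 1) function evaluations."""
    x = np.asarray(x, float)
    p = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xmm = x.copy()
            xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class SterilityModel:
    """A sterility mixed model bound to one dataset.

    Construct from a :class:`SeedCountDataset` (or a long-format DataFrame)
    and a :class:`ModelSpec`; call :meth:`fit` for a :class:`FitResult`.
    ``response_col`` selects the modelled column (the threshold analysis
    passes its 0/1 ``success`` column; count models use ``seed_count``).
    """

    def __init__(self, data, spec: ModelSpec, response_col: str = "seed_count"):
        df = data.df if isinstance(data, SeedCountDataset) else pd.DataFrame(data)
        if len(df) == 0:
            raise ValueError("empty dataset")
        if response_col not in df.columns:
            raise ValueError(f"response column {response_col!r} not in data")
        self.spec = spec
        self.data = df.reset_index(drop=True)
        self.response_col = response_col

        self.genotypes = sorted(self.data["genotype"].astype(str).unique())
        gcodes = pd.Categorical(
            self.data["genotype"].astype(str), categories=self.genotypes
        ).codes
        self._g = np.asarray(gcodes, dtype=np.int64)
        self.n_genotypes = len(self.genotypes)

        self.blocks = sorted(self.data["block"].astype(str).unique())
        self._b = np.asarray(
            pd.Categorical(self.data["block"].astype(str), categories=self.blocks).codes,
            dtype=np.int64,
        )
        plot_key = (
            self.data["genotype"].astype(str) + "\x1f" + self.data["block"].astype(str)
        )
        self.plots = sorted(plot_key.unique())
        self._p = np.asarray(
            pd.Categorical(plot_key, categories=self.plots).codes, dtype=np.int64
        )

        y = self.data[response_col].to_numpy()
        if spec.family in BINARY_FAMILIES:
            uniq = np.unique(y)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("binary families need a 0/1 response")
            self.y = y.astype(float)
        elif spec.family == "gaussian":
            self.y = TransformSpec(spec.transform).forward(y.astype(float))
        else:
            if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
                raise ValueError("count families need nonnegative integer responses")
            self.y = y.astype(float)

        if spec.random_block and len(self.blocks) < 2:
            warnings.warn(
                "fewer than 2 blocks: block variance not estimable, fixing sigma_b=0"
            )
            self.spec = dataclasses.replace(spec, random_block=False)

        self.param_names = self._make_param_names()
        self.n_params = len(self.param_names)
        self._mode_cache: dict = {}

        obs_per_g = np.bincount(self._g, minlength=self.n_genotypes)
        if np.any(obs_per_g < 2):
            warnings.warn(
                "fewer than 2 observations for some genotype(s); their effects "
                "may be poorly estimated"
            )

    # -- convenience constructor ------------------------------------------
    @classmethod
    def from_dataframe(cls, df, family: str, **spec_kwargs):
        response_col = spec_kwargs.pop("response_col", "seed_count")
        return cls(df, ModelSpec(family=family, **spec_kwargs), response_col)

    # -- parameter bookkeeping --------------------------------------------
    def _make_param_names(self):
        spec = self.spec
        names = [f"alpha[{g}]" for g in self.genotypes]
        if spec.family == "gaussian":
            names.append("log_sigma_e")
        if spec.inflation == "single":
            names.append("logit_pi")
        elif spec.inflation == "per_genotype":
            names += [f"logit_pi[{g}]" for g in self.genotypes]
        if spec.family in ("negbin", "zinb", "hnb"):
            names.append("log_k")
        if spec.random_block:
            names.append("log_sigma_b")
        if spec.random_wholeplot:
            names.append("log_sigma_ab")
        return names

    def _unpack(self, theta):
        theta = np.asarray(theta, float)
        if theta.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} parameters ({self.param_names}), got {theta.size}"
            )
        spec = self.spec
        G = self.n_genotypes
        pos = G
        out = {"alpha": theta[:G]}
        if spec.family == "gaussian":
            out["sigma_e2"] = math.exp(2 * theta[pos])
            pos += 1
        if spec.inflation == "single":
            out["pi_obs"] = np.full(len(self.y), special.expit(theta[pos]))
            pos += 1
        elif spec.inflation == "per_genotype":
            out["pi_obs"] = special.expit(theta[pos : pos + G])[self._g]
            out["pi_by_g"] = special.expit(theta[pos : pos + G])
            pos += G
        if spec.family in ("negbin", "zinb", "hnb"):
            out["k"] = math.exp(theta[pos])
            pos += 1
        if spec.random_block:
            out["sigma_b2"] = math.exp(2 * theta[pos])
            pos += 1
        if spec.random_wholeplot:
            out["sigma_ab2"] = math.exp(2 * theta[pos])
            pos += 1
        return out

    def params_to_vector(self, params: dict) -> np.ndarray:
        """Build a parameter vector from a ``{name: value}`` mapping."""
        return np.array([params[n] for n in self.param_names], float)

    # -- likelihood --------------------------------------------------------
    def loglike(self, theta) -> float:
        """Marginal log-likelihood at ``theta`` (random effects integrated out).

        For the gaussian family this is the exact marginal normal
        log-density at the given parameters (the REML criterion is used
        internally by :meth:`fit` but :meth:`loglike` is the ML quantity).
        """
        u = self._unpack(theta)
        if self.spec.family == "gaussian":
            return self._gaussian_ml_loglike(u)
        return self._integrated_loglike(u)

    def _cond(self, eta, u):
        return _cond_terms(
            self.spec.family, self.y, eta, k=u.get("k"), pi=u.get("pi_obs")
        )

    def _integrated_loglike(self, u) -> float:
        spec = self.spec
        eta0 = u["alpha"][self._g]
        s2b = u.get("sigma_b2", 0.0) if spec.random_block else 0.0
        s2p = u.get("sigma_ab2", 0.0) if spec.random_wholeplot else 0.0
        have_b = s2b > _SIGMA_ZERO2
        have_p = s2p > _SIGMA_ZERO2
        if not have_b and not have_p:
            ll, _, _ = self._cond(eta0, u)
            return float(np.sum(ll))
        if have_b != have_p:
            gi = self._b if have_b else self._p
            s2 = s2b if have_b else s2p
            n_groups = len(self.blocks) if have_b else len(self.plots)
            if spec.estimation == "ml_agq":
                return self._single_level_agq(u, eta0, gi, n_groups, s2)
            return self._single_level_laplace(u, eta0, gi, n_groups, s2)[0]
        if spec.estimation == "ml_agq":
            return self._nested_agq(u, eta0, s2b, s2p)
        return self._nested_laplace(u, eta0, s2b, s2p)

    # .. one random-effect level ..........................................
    def _penalized(self, u, eta0, gi, n_groups, s2, b):
        ll, d1, d2 = self._cond(eta0 + b[gi], u)
        pen = np.bincount(gi, weights=ll, minlength=n_groups)
        pen += -0.5 * b * b / s2 - 0.5 * math.log(2 * math.pi * s2)
        g = np.bincount(gi, weights=d1, minlength=n_groups) - b / s2
        h = np.bincount(gi, weights=d2, minlength=n_groups) - 1.0 / s2
        return pen, g, h

    def _find_modes(self, u, eta0, gi, n_groups, s2, cache_key):
        b = self._mode_cache.get(cache_key)
        if b is None or b.shape != (n_groups,):
            b = np.zeros(n_groups)
        pen, g, h = self._penalized(u, eta0, gi, n_groups, s2, b)
        for _ in range(100):
            step = g / np.minimum(h, -1e-10)  # Newton: b <- b - g/h
            for _ in range(30):  # per-group step halving
                b_new = b - step
                pen_new, g_new, h_new = self._penalized(u, eta0, gi, n_groups, s2, b_new)
                worse = pen_new < pen - 1e-12
                if not np.any(worse):
                    break
                step = np.where(worse, 0.5 * step, step)
            b, pen, g, h = b_new, pen_new, g_new, h_new
            if np.max(np.abs(g)) < 1e-9:
                break
        self._mode_cache[cache_key] = b.copy()
        return b, pen, g, h

    def _single_level_laplace(self, u, eta0, gi, n_groups, s2):
        key = ("1l", "block" if gi is self._b else "plot")
        b, pen, g, h = self._find_modes(u, eta0, gi, n_groups, s2, key)
        h_safe = np.minimum(h, -1e-10)
        ll = float(np.sum(pen + 0.5 * math.log(2 * math.pi) - 0.5 * np.log(-h_safe)))
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite Laplace marginal log-likelihood")
        return ll, b, h_safe

    def _single_level_agq(self, u, eta0, gi, n_groups, s2):
        _, bhat, h_safe = self._single_level_laplace(u, eta0, gi, n_groups, s2)
        s_l = 1.0 / np.sqrt(-h_safe)
        x, w = np.polynomial.hermite.hermgauss(self.spec.agq_nodes)
        vals = np.empty((self.spec.agq_nodes, n_groups))
        for m, (xm, wm) in enumerate(zip(x, w)):
            bm = bhat + math.sqrt(2.0) * s_l * xm
            pen, _, _ = self._penalized(u, eta0, gi, n_groups, s2, bm)
            vals[m] = pen + xm * xm + math.log(wm)
        out = logsumexp(vals, axis=0) + np.log(math.sqrt(2.0) * s_l)
        return float(np.sum(out))

    # .. nested (block + whole-plot) ......................................
    def _block_layout(self):
        """Per-block observation and plot indexing (cached)."""
        lay = self._mode_cache.get("layout")
        if lay is not None:
            return lay
        lay = []
        for j in range(len(self.blocks)):
            obs = np.flatnonzero(self._b == j)
            plots_j, local = np.unique(self._p[obs], return_inverse=True)
            lay.append((obs, plots_j, local))
        self._mode_cache["layout"] = lay
        return lay

    def _nested_laplace(self, u, eta0, s2b, s2p):
        total = 0.0
        for j, (obs, plots_j, local) in enumerate(self._block_layout()):
            P = len(plots_j)
            v = self._mode_cache.get(("2l", j))
            if v is None or v.shape != (P + 1,):
                v = np.zeros(P + 1)
            yj_eta0 = eta0[obs]

            def pen_parts(v):
                b, uu = v[0], v[1:]
                eta = yj_eta0 + b + uu[local]
                ll, d1, d2 = _cond_terms(
                    self.spec.family,
                    self.y[obs],
                    eta,
                    k=u.get("k"),
                    pi=None if u.get("pi_obs") is None else u["pi_obs"][obs],
                )
                pen = (
                    float(np.sum(ll))
                    - 0.5 * b * b / s2b
                    - 0.5 * float(np.sum(uu * uu)) / s2p
                    - 0.5 * math.log(2 * math.pi * s2b)
                    - 0.5 * P * math.log(2 * math.pi * s2p)
                )
                gb = float(np.sum(d1)) - b / s2b
                gu = np.bincount(local, weights=d1, minlength=P) - uu / s2p
                hbb = float(np.sum(d2)) - 1.0 / s2b
                hup = np.bincount(local, weights=d2, minlength=P)
                huu = hup - 1.0 / s2p
                return pen, np.concatenate(([gb], gu)), hbb, hup, huu

            pen, grad, hbb, hup, huu = pen_parts(v)
            for _ in range(100):
                H = np.empty((P + 1, P + 1))
                H[0, 0] = min(hbb, -1e-10)
                H[0, 1:] = H[1:, 0] = hup
                H[1:, 1:] = np.diag(np.minimum(huu, -1e-10))
                try:
                    step = np.linalg.solve(H, grad)
                except np.linalg.LinAlgError:
                    step = grad / np.concatenate(([H[0, 0]], np.diag(H)[1:]))
                scale = 1.0
                for _ in range(30):
                    v_new = v - scale * step
                    pen_new, grad_new, hbb_n, hup_n, huu_n = pen_parts(v_new)
                    if pen_new >= pen - 1e-12 or scale < 1e-6:
                        break
                    scale *= 0.5
                v, pen, grad, hbb, hup, huu = v_new, pen_new, grad_new, hbb_n, hup_n, huu_n
                if np.max(np.abs(grad)) < 1e-9:
                    break
            self._mode_cache[("2l", j)] = v.copy()
            H = np.empty((P + 1, P + 1))
            H[0, 0] = min(hbb, -1e-10)
            H[0, 1:] = H[1:, 0] = hup
            H[1:, 1:] = np.diag(np.minimum(huu, -1e-10))
            sign, logdet = np.linalg.slogdet(-H)
            if sign <= 0:  # safeguarded curvature: diagonal fallback
                logdet = float(np.sum(np.log(-np.minimum(np.diag(H), -1e-10))))
            total += pen + 0.5 * (P + 1) * math.log(2 * math.pi) - 0.5 * logdet
        if not np.isfinite(total):
            raise FloatingPointError("non-finite Laplace marginal log-likelihood")
        return float(total)

    def _nested_agq(self, u, eta0, s2b, s2p):
        """Adaptive GH over the block effect; inner whole-plot integrals by
        adaptive GH at each outer node (plots are conditionally independent
        given the block effect)."""
        nodes = self.spec.agq_nodes
        x, w = np.polynomial.hermite.hermgauss(nodes)
        total = 0.0
        for j, (obs, plots_j, local) in enumerate(self._block_layout()):
            P = len(plots_j)
            yj = self.y[obs]
            eta0j = eta0[obs]
            pij = None if u.get("pi_obs") is None else u["pi_obs"][obs]

            def inner_pen(uu, b):
                eta = eta0j + b + uu[local]
                ll, d1, d2 = _cond_terms(self.spec.family, yj, eta, k=u.get("k"), pi=pij)
                pen = (
                    np.bincount(local, weights=ll, minlength=P)
                    - 0.5 * uu * uu / s2p
                    - 0.5 * math.log(2 * math.pi * s2p)
                )
                g = np.bincount(local, weights=d1, minlength=P) - uu / s2p
                h = np.bincount(local, weights=d2, minlength=P) - 1.0 / s2p
                return pen, g, h

            def log_inner(b):
                """Vector of log integrals over u_p given the block effect."""
                uu = np.zeros(P)
                pen, g, h = inner_pen(uu, b)
                for _ in range(60):
                    step = g / np.minimum(h, -1e-10)
                    for _ in range(20):
                        uu_new = uu - step
                        pen_new, g_new, h_new = inner_pen(uu_new, b)
                        worse = pen_new < pen - 1e-12
                        if not np.any(worse):
                            break
                        step = np.where(worse, 0.5 * step, step)
                    uu, pen, g, h = uu_new, pen_new, g_new, h_new
                    if np.max(np.abs(g)) < 1e-9:
                        break
                s_l = 1.0 / np.sqrt(-np.minimum(h, -1e-10))
                vals = np.empty((nodes, P))
                for m, (xm, wm) in enumerate(zip(x, w)):
                    pen_m, _, _ = inner_pen(uu + math.sqrt(2.0) * s_l * xm, b)
                    vals[m] = pen_m + xm * xm + math.log(wm)
                return logsumexp(vals, axis=0) + np.log(math.sqrt(2.0) * s_l)

            def outer(b):
                return (
                    float(np.sum(log_inner(b)))
                    - 0.5 * b * b / s2b
                    - 0.5 * math.log(2 * math.pi * s2b)
                )

            res = optimize.minimize_scalar(
                lambda b: -outer(b),
                bounds=(-6 * math.sqrt(s2b), 6 * math.sqrt(s2b)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            bhat = float(res.x)
            hstep = 1e-3 * max(math.sqrt(s2b), 1e-3)
            f0, fp, fm = outer(bhat), outer(bhat + hstep), outer(bhat - hstep)
            curv = (fp - 2 * f0 + fm) / hstep**2
            s_l = 1.0 / math.sqrt(max(-curv, 1.0 / (100.0 * s2b)))
            vals = [
                outer(bhat + math.sqrt(2.0) * s_l * xm) + xm * xm + math.log(wm)
                for xm, wm in zip(x, w)
            ]
            total += logsumexp(vals) + math.log(math.sqrt(2.0) * s_l)
        return float(total)

    # .. gaussian ..........................................................
    def _gaussian_V(self, u):
        n = len(self.y)
        V = u["sigma_e2"] * np.eye(n)
        if self.spec.random_block and u.get("sigma_b2", 0.0) > _SIGMA_ZERO2:
            Zb = np.equal.outer(self._b, self._b)
            V += u["sigma_b2"] * Zb
        if self.spec.random_wholeplot and u.get("sigma_ab2", 0.0) > _SIGMA_ZERO2:
            Zp = np.equal.outer(self._p, self._p)
            V += u["sigma_ab2"] * Zp
        return V

    def _design(self):
        X = np.zeros((len(self.y), self.n_genotypes))
        X[np.arange(len(self.y)), self._g] = 1.0
        return X

    def _gaussian_ml_loglike(self, u) -> float:
        V = self._gaussian_V(u)
        r = self.y - u["alpha"][self._g]
        L = np.linalg.cholesky(V)
        z = np.linalg.solve(L, r)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        n = len(self.y)
        return -0.5 * (n * math.log(2 * math.pi) + logdet + float(z @ z))

    def _gaussian_reml(self, log_var_params):
        """REML criterion (to maximize) and GLS solution at given variances."""
        X = self._design()
        n, p = X.shape
        u = {"sigma_e2": math.exp(2 * log_var_params[0])}
        pos = 1
        if self.spec.random_block:
            u["sigma_b2"] = math.exp(2 * log_var_params[pos])
            pos += 1
        if self.spec.random_wholeplot:
            u["sigma_ab2"] = math.exp(2 * log_var_params[pos])
            pos += 1
        V = self._gaussian_V(u)
        L = np.linalg.cholesky(V)
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, self.y)
        XtVX = Xi.T @ Xi
        beta = np.linalg.solve(XtVX, Xi.T @ yi)
        r = yi - Xi @ beta
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        sign, logdetX = np.linalg.slogdet(XtVX)
        reml = -0.5 * (
            (n - p) * math.log(2 * math.pi) + logdetV + logdetX + float(r @ r)
        )
        return reml, beta, np.linalg.inv(XtVX), u

    # -- fitting -----------------------------------------------------------
    def _start_values(self):
        spec = self.spec
        y = self.y
        G = self.n_genotypes
        means = np.array(
            [max(float(np.mean(y[self._g == i])), 1e-3) if np.any(self._g == i) else 1e-3
             for i in range(G)]
        )
        theta = []
        if spec.family == "gaussian":
            theta += list(means)
            theta.append(0.5 * math.log(max(float(np.var(y)), 1e-6)))
        elif spec.family in BINARY_FAMILIES:
            fwd = link("logit" if spec.family == "binary_logit" else "probit")[0]
            n_g = np.array([max(int(np.sum(self._g == i)), 1) for i in range(G)])
            pr = np.clip(means, 1.0 / (2 * n_g), 1.0 - 1.0 / (2 * n_g))
            theta += list(np.clip(fwd(pr), -5, 5))
        else:
            pos_means = np.array(
                [
                    float(np.mean(y[(self._g == i) & (y > 0)]))
                    if np.any((self._g == i) & (y > 0))
                    else max(means[i], 0.5)
                    for i in range(G)
                ]
            )
            base = pos_means if spec.family in MIXTURE_FAMILIES else means
            theta += list(np.log(np.clip(base, 1e-2, None)))
        zero_frac = np.array(
            [float(np.mean(y[self._g == i] == 0)) if np.any(self._g == i) else 0.5
             for i in range(G)]
        )
        if spec.inflation == "single":
            z = float(np.mean(y == 0))
            p0 = z if spec.family == "hnb" else 0.7 * z
            theta.append(float(special.logit(np.clip(p0, 0.02, 0.95))))
        elif spec.inflation == "per_genotype":
            p0 = zero_frac if spec.family == "hnb" else 0.7 * zero_frac
            theta += list(special.logit(np.clip(p0, 0.02, 0.95)))
        if spec.family in ("negbin", "zinb", "hnb"):
            yp = y[y > 0] if spec.family in MIXTURE_FAMILIES else y
            m, v = (float(np.mean(yp)), float(np.var(yp))) if yp.size > 1 else (1.0, 2.0)
            k0 = m * m / (v - m) if v > m else 10.0
            theta.append(math.log(float(np.clip(k0, 0.1, 50.0))))
        if spec.random_block:
            theta.append(math.log(0.3))
        if spec.random_wholeplot:
            theta.append(math.log(0.3))
        return np.array(theta)

    def _bounds(self):
        spec = self.spec
        bounds = []
        for name in self.param_names:
            if name.startswith("alpha"):
                bounds.append(
                    (None, None) if spec.family == "gaussian" else _ALPHA_BOUNDS
                )
            elif name.startswith("logit_pi"):
                bounds.append(_LOGIT_PI_BOUNDS)
            elif name == "log_k":
                bounds.append(_LOG_K_BOUNDS)
            elif name.startswith("log_sigma_e"):
                bounds.append((None, None))
            else:  # log_sigma_b / log_sigma_ab
                bounds.append(_LOG_SIGMA_BOUNDS)
        return bounds

    def fit(self, start_params=None, maxiter: int = 500, n_restarts: int | None = None):
        """Maximize the marginal likelihood (REML for gaussian).

        Deterministic given the data and starting values; mixture families
        retry from deterministically perturbed starts when the first
        optimization fails.  Never raises on non-convergence: the returned
        :class:`FitResult` carries ``converged=False`` instead.
        """
        if self.spec.family == "gaussian":
            return self._fit_gaussian()
        if n_restarts is None:
            n_restarts = 4 if self.spec.family in MIXTURE_FAMILIES else 1
        x0 = np.asarray(start_params, float) if start_params is not None else self._start_values()
        bounds = self._bounds()

        def nll(theta):
            try:
                val = -self.loglike(theta)
            except FloatingPointError:
                return 1e10
            return val if np.isfinite(val) else 1e10

        best = None
        rng = np.random.default_rng(20150402)  # fixed: restarts are deterministic
        for attempt in range(n_restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.5, size=x0.size)
            start = np.array(
                [np.clip(s, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
                 for s, (lo, hi) in zip(start, bounds)]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    nll,
                    start,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7, "eps": 1e-6},
                )
            if best is None or res.fun < best.fun - 1e-8:
                best = res
            if best.success:
                break
        theta = np.asarray(best.x, float)
        ll = -float(best.fun)
        grad_norm = float(np.max(np.abs(_numdiff_grad(nll, theta, step=1e-5))))
        H = _numdiff_hessian(lambda t: -nll(t), theta, step=1e-4)
        return self._build_result(theta, ll, H, bool(best.success), grad_norm, str(best.message))

    def _fit_gaussian(self):
        n_var = 1 + int(self.spec.random_block) + int(self.spec.random_wholeplot)
        x0 = np.full(n_var, 0.5 * math.log(max(float(np.var(self.y)), 1e-6)))
        if n_var == 1:
            # closed form: OLS + REML residual variance
            X = self._design()
            n, p = X.shape
            counts = np.maximum(np.bincount(self._g, minlength=p), 1)
            beta = np.bincount(self._g, weights=self.y, minlength=p) / counts
            resid = self.y - beta[self._g]
            dof = max(n - p, 1)
            s2 = float(resid @ resid) / dof
            lv = np.array([0.5 * math.log(max(s2, 1e-300))])
            reml, beta, covb, u = self._gaussian_reml(lv)
            theta = np.concatenate([beta, lv])
            H = None
            cov = np.zeros((len(theta), len(theta)))
            cov[:p, :p] = covb
            cov[p, p] = 1.0 / (2.0 * dof)  # var of log sigma_e
            return self._finish_gaussian(theta, reml, cov, True, 0.0, "closed form")
        bounds = [(None, None)] + [_LOG_SIGMA_BOUNDS] * (n_var - 1)

        def nreml(lv):
            try:
                return -self._gaussian_reml(lv)[0]
            except np.linalg.LinAlgError:
                return 1e10

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nreml, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8},
            )
        reml, beta, covb, u = self._gaussian_reml(res.x)
        theta = np.concatenate([beta, res.x])
        p = self.n_genotypes
        Hv = _numdiff_hessian(lambda lv: -nreml(lv), res.x, step=1e-4)
        cov = np.zeros((len(theta), len(theta)))
        cov[:p, :p] = covb
        try:
            cov[p:, p:] = np.linalg.inv(-Hv)
        except np.linalg.LinAlgError:
            cov[p:, p:] = np.linalg.pinv(-Hv)
        grad = float(np.max(np.abs(_numdiff_grad(nreml, res.x, step=1e-5))))
        return self._finish_gaussian(theta, reml, cov, bool(res.success), grad, str(res.message))

    def _finish_gaussian(self, theta, ll, cov, success, grad_norm, message):
        result = FitResult(
            model=self,
            params=pd.Series(theta, index=self.param_names),
            cov_params=pd.DataFrame(cov, index=self.param_names, columns=self.param_names),
            loglik=float(ll),
            n_params=len(theta),
            n_obs=len(self.y),
            converged=success,
            gradient_norm=grad_norm,
            hessian_condition=float(np.linalg.cond(cov)) if np.all(np.isfinite(cov)) else np.inf,
            message=message,
        )
        result._detect_flags()
        return result

    def _build_result(self, theta, ll, H, success, grad_norm, message):
        with np.errstate(all="ignore"):
            try:
                cov = np.linalg.inv(-H)
                if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                    raise np.linalg.LinAlgError
                singular = False
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(-(H + H.T) / 2.0, rcond=1e-12)
                singular = True
            cond = float(np.linalg.cond(H)) if np.all(np.isfinite(H)) else np.inf
        result = FitResult(
            model=self,
            params=pd.Series(theta, index=self.param_names),
            cov_params=pd.DataFrame(cov, index=self.param_names, columns=self.param_names),
            loglik=float(ll),
            n_params=len(theta),
            n_obs=len(self.y),
            converged=bool(success),
            gradient_norm=float(grad_norm),
            hessian_condition=cond,
            message=message,
        )
        if singular:
            result.flags["messages"].append("information matrix singular; pseudo-inverse used")
        result._detect_flags()
        return result


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

InformationCriteria = namedtuple("InformationCriteria", ["aicc", "bic", "minus2ll"])


@dataclasses.dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of a fitted sterility model."""

    model: SterilityModel
    params: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    gradient_norm: float
    hessian_condition: float
    message: str = ""
    flags: dict = dataclasses.field(
        default_factory=lambda: {"non_estimable": [], "boundary": [], "messages": []}
    )

    # -- flags -------------------------------------------------------------
    def _detect_flags(self) -> None:
        se = self.bse
        for name in self.params.index:
            val = self.params[name]
            if name.startswith("alpha") and self.model.spec.family != "gaussian":
                lo, hi = _ALPHA_BOUNDS
            elif name.startswith("logit_pi"):
                lo, hi = _LOGIT_PI_BOUNDS
            elif name == "log_k":
                lo, hi = _LOG_K_BOUNDS
            elif name.startswith("log_sigma") and name != "log_sigma_e":
                lo, hi = _LOG_SIGMA_BOUNDS
            else:
                continue
            if val <= lo + 1e-6 or val >= hi - 1e-6:
                self.flags["boundary"].append(name)
        for name in self.params.index:
            if not np.isfinite(se[name]) or se[name] > 1e3 or (
                name in self.flags["boundary"]
            ):
                if name not in self.flags["non_estimable"]:
                    self.flags["non_estimable"].append(name)
        if self.hessian_condition > 1e12:
            self.flags["messages"].append(
                f"ill-conditioned information matrix (cond={self.hessian_condition:.2e})"
            )

    # -- simple accessors ----------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov_params.to_numpy()), 0.0, None)),
            index=self.params.index,
        )

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def alpha(self) -> pd.Series:
        """Genotype fixed effects on the link scale."""
        names = [f"alpha[{g}]" for g in self.model.genotypes]
        return pd.Series(self.params[names].to_numpy(), index=self.model.genotypes)

    def variance_components(self) -> dict:
        out = {}
        if "log_sigma_b" in self.params.index:
            out["sigma_b2"] = float(math.exp(2 * self.params["log_sigma_b"]))
        if "log_sigma_ab" in self.params.index:
            out["sigma_ab2"] = float(math.exp(2 * self.params["log_sigma_ab"]))
        if "log_sigma_e" in self.params.index:
            out["sigma_e2"] = float(math.exp(2 * self.params["log_sigma_e"]))
        return out

    @property
    def k(self) -> float | None:
        if "log_k" in self.params.index:
            return float(math.exp(self.params["log_k"]))
        return None

    # -- information criteria ------------------------------------------------
    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        n, p = self.n_obs, self.n_params
        if n <= p + 1:
            warnings.warn("AICc undefined: n <= p + 1")
            return float("nan")
        return self.aic + 2.0 * p * (p + 1) / (n - p - 1)

    @property
    def bic(self) -> float:
        return self.minus2ll + self.n_params * math.log(self.n_obs)

    # -- genotype-level summaries (delegate to count_models/threshold ops) ---
    def genotype_means(self, level: float = 0.95):
        from .counts import genotype_count_means

        return genotype_count_means(self, level=level)

    def inflation_probabilities(self, level: float = 0.95):
        from .counts import inflation_probabilities

        return inflation_probabilities(self, level=level)

    # -- serialization / display ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "name": self.spec.name,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "gradient_norm": self.gradient_norm,
            "hessian_condition": self.hessian_condition,
            "aicc": None if np.isnan(self.aicc) else self.aicc,
            "bic": self.bic,
            "flags": self.flags,
        }

    def summary(self) -> str:
        lines = [
            f"Sterility mixed model: family={self.spec.family} "
            f"({self.spec.name}), estimation={self.spec.estimation}",
            f"n_obs={self.n_obs}  n_params={self.n_params}  "
            f"loglik={self.loglik:.3f}  AICc={self.aicc:.2f}  BIC={self.bic:.2f}",
            f"converged={self.converged}  |grad|={self.gradient_norm:.2e}  "
            f"cond(H)={self.hessian_condition:.2e}",
            "-" * 64,
            f"{'parameter':<28}{'estimate':>12}{'std err':>12}",
        ]
        se = self.bse
        for name in self.params.index:
            star = " *" if name in self.flags["non_estimable"] else ""
            lines.append(f"{name:<28}{self.params[name]:>12.4f}{se[name]:>12.4f}{star}")
        if self.flags["non_estimable"]:
            lines.append("* flagged non-estimable (boundary or unstable curvature)")
        for msg in self.flags["messages"]:
            lines.append(f"note: {msg}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level operations (spec surface)
# ---------------------------------------------------------------------------

def marginal_loglik(spec: ModelSpec, params, data, response_col: str = "seed_count") -> float:
    """Marginal log-likelihood of ``params`` (vector or ``{name: value}``)."""
    model = SterilityModel(data, spec, response_col=response_col)
    if isinstance(params, dict):
        params = model.params_to_vector(params)
    return model.loglike(params)


def fit(spec: ModelSpec, data, response_col: str = "seed_count", **kwargs) -> FitResult:
    """Fit ``spec`` to ``data``; see :meth:`SterilityModel.fit`."""
    return SterilityModel(data, spec, response_col=response_col).fit(**kwargs)


def information_criteria(result: FitResult) -> InformationCriteria:
    """(AICc, BIC, -2LL): AICc = -2l + 2p + 2p(p+1)/(n-p-1); BIC = -2l + p ln n."""
    return InformationCriteria(result.aicc, result.bic, result.minus2ll)


def _family_mean_var(result: FitResult):
    """Per-observation fitted data-scale mean and variance function."""
    model = result.model
    u = model._unpack(result.params.to_numpy())
    spec = model.spec
    eta = u["alpha"][model._g]
    # condition on random-effect modes where present
    s2b = u.get("sigma_b2", 0.0) if spec.random_block else 0.0
    s2p = u.get("sigma_ab2", 0.0) if spec.random_wholeplot else 0.0
    if s2b > _SIGMA_ZERO2 and s2p <= _SIGMA_ZERO2:
        _, b, _ = model._single_level_laplace(u, eta, model._b, len(model.blocks), s2b)
        eta = eta + b[model._b]
    elif s2p > _SIGMA_ZERO2 and s2b <= _SIGMA_ZERO2:
        _, b, _ = model._single_level_laplace(u, eta, model._p, len(model.plots), s2p)
        eta = eta + b[model._p]
    elif s2b > _SIGMA_ZERO2 and s2p > _SIGMA_ZERO2:
        model._nested_laplace(u, eta, s2b, s2p)  # refresh mode cache
        for j, (obs, plots_j, local) in enumerate(model._block_layout()):
            v = model._mode_cache[("2l", j)]
            eta = eta.copy()
            eta[obs] += v[0] + v[1:][local]
    lam = np.exp(eta)
    k = u.get("k", math.inf)
    if spec.family == "poisson":
        return lam, lam
    if spec.family == "negbin":
        return lam, lam + lam**2 / k
    pi = u["pi_obs"]
    if spec.family == "zinb":
        mean = (1.0 - pi) * lam
        var = (1.0 - pi) * lam * (1.0 + lam / k) + pi * (1.0 - pi) * lam**2
        return mean, var
    if spec.family == "hnb":
        f0 = (k / (k + lam)) ** k
        mean_pos = lam / (1.0 - f0)
        e_y2_base = lam + lam**2 + lam**2 / k  # E[Y^2] of untruncated NB
        mean = (1.0 - pi) * mean_pos
        var = (1.0 - pi) * e_y2_base / (1.0 - f0) - mean**2
        return mean, var
    raise ValueError("Pearson overdispersion is defined for count families")


def pearson_overdispersion(result: FitResult) -> float:
    """Pearson chi-square / d.f.: sum((y - mu)^2 / v(mu)) / (n - p).

    ``v`` is the family variance function on the data scale; observations
    with ``v(mu) = 0`` are excluded with a warning.  Values well above 1 for
    a Poisson fit indicate overdispersion.
    """
    if result.spec.family not in COUNT_FAMILIES:
        raise ValueError("Pearson overdispersion applies to count-family fits")
    mean, var = _family_mean_var(result)
    y = result.model.y
    ok = var > 0
    if not np.all(ok):
        warnings.warn(f"excluding {int(np.sum(~ok))} observation(s) with zero variance")
    dof = max(result.n_obs - result.n_params, 1)
    return float(np.sum((y[ok] - mean[ok]) ** 2 / var[ok]) / dof)
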