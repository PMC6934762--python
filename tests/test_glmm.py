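"""GLMM engine: marginal likelihood against independent oracles, optimizer
behaviour on degenerate data, information criteria, and the Pearson
overdispersion diagnostic."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, gammaln
from scipy.stats import multivariate_normal

from sterilecount import (
    ModelSpec,
    SterilityModel,
    information_criteria,
    marginal_loglik,
    pearson_overdispersion,
)

from conftest import make_df, zi_dataset


# ---------------------------------------------------------------------------
# independent oracles (dense, non-adaptive quadrature / closed forms)
# ---------------------------------------------------------------------------

def dense_gh_logit(df, alphas, sigma, nodes=41, response="seed_count"):
    """Brute-force marginal loglik: non-adaptive Gauss-Hermite per block."""
    x, w = hermgauss(nodes)
    total = 0.0
    for blk in sorted(df["block"].unique()):
        sub = df[df["block"] == blk]
        a = np.array([alphas[g] for g in sub["genotype"]])
        s = sub[response].to_numpy()
        vals = []
        for xm, wm in zip(x, w):
            p = expit(a + math.sqrt(2) * sigma * xm)
            vals.append(wm * np.prod(np.where(s == 1, p, 1 - p)))
        total += math.log(sum(vals) / math.sqrt(math.pi))
    return total


def dense_gh_poisson(df, alphas, sigma, nodes=61):
    x, w = hermgauss(nodes)
    total = 0.0
    for blk in sorted(df["block"].unique()):
        sub = df[df["block"] == blk]
        a = np.array([alphas[g] for g in sub["genotype"]])
        y = sub["seed_count"].to_numpy()
        vals = []
        for xm, wm in zip(x, w):
            mu = np.exp(a + math.sqrt(2) * sigma * xm)
            vals.append(wm * math.exp(float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))))
        total += math.log(sum(vals) / math.sqrt(math.pi))
    return total


BINARY_TOY = make_df(
    [("s", "g1", "B1", "H1", 1), ("s", "g2", "B1", "H2", 0), ("s", "g1", "B1", "H3", 1),
     ("s", "g2", "B1", "H4", 0), ("s", "g1", "B1", "H5", 0),
     ("s", "g1", "B2", "H1", 0), ("s", "g2", "B2", "H2", 1), ("s", "g1", "B2", "H3", 0),
     ("s", "g2", "B2", "H4", 1), ("s", "g1", "B2", "H5", 1)]
)
TOY_ALPHAS = {"g1": 0.3, "g2": -0.2}


class TestMarginalLoglik:
    def test_zero_variance_collapses_to_conditional_sum(self):
        """With sigma_b = sigma_ab = 0 the integral is the conditional sum."""
        df = make_df([("s", "g1", "B1", f"H{i}", y) for i, y in enumerate([2, 0, 5, 1])])
        spec = ModelSpec(family="poisson", random_block=True, random_wholeplot=True)
        ll = marginal_loglik(
            spec,
            {"alpha[g1]": 0.8, "log_sigma_b": -30.0, "log_sigma_ab": -30.0},
            df,
        )
        y = np.array([2, 0, 5, 1], float)
        mu = math.exp(0.8)
        expected = float(np.sum(y * 0.8 - mu - gammaln(y + 1)))
        assert ll == expected

    def test_laplace_against_dense_oracle_binary(self):
        """Laplace in its valid regime (sigma^2 = 1/16, 5 obs/block)."""
        sigma2 = 0.0625
        m = SterilityModel(BINARY_TOY, ModelSpec(family="binary_logit", random_block=True))
        ll = m.loglike(m.params_to_vector(
            {**{f"alpha[{g}]": a for g, a in TOY_ALPHAS.items()},
             "log_sigma_b": 0.5 * math.log(sigma2)}))
        oracle = dense_gh_logit(BINARY_TOY, TOY_ALPHAS, math.sqrt(sigma2))
        assert abs(ll - oracle) < 1e-3

    def test_agq_against_dense_oracle_binary(self):
        sigma2 = 0.25
        spec = ModelSpec(family="binary_logit", random_block=True,
                         estimation="ml_agq", agq_nodes=21)
        m = SterilityModel(BINARY_TOY, spec)
        ll = m.loglike(m.params_to_vector(
            {**{f"alpha[{g}]": a for g, a in TOY_ALPHAS.items()},
             "log_sigma_b": 0.5 * math.log(sigma2)}))
        oracle = dense_gh_logit(BINARY_TOY, TOY_ALPHAS, math.sqrt(sigma2))
        assert abs(ll - oracle) < 1e-8

    def test_laplace_approximation_error_documented(self):
        """At sigma^2 = 0.25 with 5 Bernoulli obs/block the Laplace error is
        real (~5e-3) and adaptive quadrature removes it."""
        sigma2 = 0.25
        theta = {**{f"alpha[{g}]": a for g, a in TOY_ALPHAS.items()},
                 "log_sigma_b": 0.5 * math.log(sigma2)}
        oracle = dense_gh_logit(BINARY_TOY, TOY_ALPHAS, math.sqrt(sigma2))
        lap = marginal_loglik(
            ModelSpec(family="binary_logit", random_block=True), theta, BINARY_TOY)
        agq = marginal_loglik(
            ModelSpec(family="binary_logit", random_block=True,
                      estimation="ml_agq", agq_nodes=21), theta, BINARY_TOY)
        assert 1e-4 < abs(lap - oracle) < 2e-2
        assert abs(agq - oracle) < 1e-6
        assert abs(lap - agq) < 1e-2  # Laplace and AGQ agree to ~1e-2 here

    def test_poisson_laplace_and_agq_against_oracle(self):
        df = make_df(
            [("s", "g1", "B1", f"H{i}", y) for i, y in enumerate([3, 5, 2, 4, 6])]
            + [("s", "g1", "B2", f"H{i}", y) for i, y in enumerate([1, 2, 4, 3, 2])]
        )
        theta = {"alpha[g1]": 1.0, "log_sigma_b": 0.5 * math.log(0.04)}
        oracle = dense_gh_poisson(df, {"g1": 1.0}, 0.2)
        lap = marginal_loglik(ModelSpec(family="poisson", random_block=True), theta, df)
        agq = marginal_loglik(
            ModelSpec(family="poisson", random_block=True, estimation="ml_agq",
                      agq_nodes=31), theta, df)
        assert abs(lap - oracle) < 1e-3
        assert abs(agq - oracle) < 1e-8

    def test_agq_converges_monotonically_to_dense_reference(self):
        sigma2 = 0.25
        theta = {**{f"alpha[{g}]": a for g, a in TOY_ALPHAS.items()},
                 "log_sigma_b": 0.5 * math.log(sigma2)}
        ref = dense_gh_logit(BINARY_TOY, TOY_ALPHAS, math.sqrt(sigma2), nodes=101)
        errs = []
        for nodes in (1, 3, 5, 9, 15):
            ll = marginal_loglik(
                ModelSpec(family="binary_logit", random_block=True,
                          estimation="ml_agq", agq_nodes=nodes), theta, BINARY_TOY)
            errs.append(abs(ll - ref))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_gaussian_matches_closed_form_marginal_normal(self):
        """Exact marginal-covariance evaluation vs scipy's mvn logpdf."""
        df = make_df(
            [("s", "g1", "B1", f"H{i}", y) for i, y in enumerate([2, 4, 1, 3, 5])]
            + [("s", "g2", "B2", f"H{i}", y) for i, y in enumerate([7, 6, 8, 9, 5])]
        )
        spec = ModelSpec(family="gaussian", random_block=True)
        model = SterilityModel(df, spec)
        theta = model.params_to_vector(
            {"alpha[g1]": 3.0, "alpha[g2]": 7.0,
             "log_sigma_e": 0.5 * math.log(2.0), "log_sigma_b": 0.5 * math.log(0.5)}
        )
        ll = model.loglike(theta)
        y = df["seed_count"].to_numpy(float)
        mean = np.where(df["genotype"] == "g1", 3.0, 7.0)
        blocks = (df["block"] == "B2").to_numpy()
        V = 2.0 * np.eye(10) + 0.5 * np.equal.outer(blocks, blocks)
        expected = multivariate_normal(mean=mean, cov=V).logpdf(y)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_invariance_to_relabeling(self):
        d = zi_dataset([0.3, 0.5], [4.0, 9.0], seed=8)
        spec = ModelSpec(family="negbin", random_block=True)
        theta = {"alpha[g0]": 1.2, "alpha[g1]": 2.0, "log_k": 0.3, "log_sigma_b": -1.0}
        ll1 = marginal_loglik(spec, theta, d)
        df2 = d.df.copy()
        df2["genotype"] = df2["genotype"].map({"g0": "zeta", "g1": "acme"})
        df2["block"] = df2["block"].map(lambda b: "X" + b)
        theta2 = {"alpha[zeta]": 1.2, "alpha[acme]": 2.0, "log_k": 0.3, "log_sigma_b": -1.0}
        ll2 = marginal_loglik(spec, theta2, df2)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_nested_laplace_close_to_nested_agq(self):
        d = zi_dataset([0.3, 0.4], [3.0, 8.0], n_blocks=3, heads=4, seed=2)
        theta = {"alpha[g0]": 1.1, "alpha[g1]": 2.1, "log_k": 0.5,
                 "log_sigma_b": 0.5 * math.log(0.04), "log_sigma_ab": 0.5 * math.log(0.04)}
        common = dict(family="negbin", random_block=True, random_wholeplot=True)
        lap = marginal_loglik(ModelSpec(**common), theta, d)
        agq = marginal_loglik(
            ModelSpec(**common, estimation="ml_agq", agq_nodes=15), theta, d)
        assert abs(lap - agq) < 1e-2


class TestFit:
    def test_negbin_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        d = zi_dataset([0.0, 0.0, 0.0], [3.0, 7.0, 15.0], k=1.5, heads=30, seed=4)
        fit = SterilityModel(d, ModelSpec(family="negbin")).fit()
        X = pd.get_dummies(d.df["genotype"]).to_numpy(float)
        ref = sm.NegativeBinomial(
            d.df["seed_count"].to_numpy(float), X, loglike_method="nb2"
        ).fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        np.testing.assert_allclose(
            np.sort(fit.alpha().to_numpy()), np.sort(ref.params[:3]), atol=1e-3
        )

    def test_zinb_matches_statsmodels(self):
        import statsmodels.discrete.count_model as cm

        d = zi_dataset([0.4], [5.0], k=2.0, heads=250, seed=6)
        fit = SterilityModel(d, ModelSpec(family="zinb", inflation="single")).fit()
        y = d.df["seed_count"].to_numpy(float)
        X = np.ones((len(y), 1))
        ref = cm.ZeroInflatedNegativeBinomialP(y, X, exog_infl=X, p=2).fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert float(fit.params["alpha[g0]"]) == pytest.approx(ref.params[1], abs=1e-3)
        assert float(fit.params["logit_pi"]) == pytest.approx(ref.params[0], abs=5e-3)

    def test_all_zero_response_flags_non_estimable(self):
        df = make_df([("s", "g1", "B1", f"H{i}", 0) for i in range(20)])
        fit = SterilityModel(df, ModelSpec(family="zinb", inflation="single")).fit()
        # pi is driven to the boundary and the count mean is unidentified
        assert fit.flags["non_estimable"]
        assert isinstance(fit.converged, bool)  # no exception, ever

    def test_overparameterized_hnb_flags_non_estimable(self):
        rows = [("s", g, "B1", "H1", y) for g, y in [("g1", 0), ("g2", 3)]]
        with pytest.warns(UserWarning):
            fit = SterilityModel(
                make_df(rows), ModelSpec(family="hnb", inflation="per_genotype")
            ).fit()
        assert fit.flags["non_estimable"]

    def test_nested_models_likelihood_ordering(self):
        d = zi_dataset([0.4, 0.3], [4.0, 10.0], k=1.5, heads=40, seed=12)
        ll_nb = SterilityModel(d, ModelSpec(family="negbin")).fit().loglik
        ll_zinb_single = SterilityModel(
            d, ModelSpec(family="zinb", inflation="single")).fit().loglik
        ll_zinb_multi = SterilityModel(
            d, ModelSpec(family="zinb", inflation="per_genotype")).fit().loglik
        assert ll_zinb_single >= ll_nb - 1e-4  # NB nested in ZINB at pi -> 0
        assert ll_zinb_multi >= ll_zinb_single - 1e-4

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(family="negbin", inflation="single")
        with pytest.raises(ValueError):
            ModelSpec(family="zinb")
        with pytest.raises(ValueError):
            ModelSpec(family="poisson", estimation="reml")
        with pytest.raises(ValueError):
            ModelSpec(family="gaussian", estimation="ml_laplace")


class TestInformationCriteria:
    def test_closed_forms(self, toy_counts):
        fit = SterilityModel(toy_counts, ModelSpec(family="poisson")).fit()
        fake = dataclasses.replace(fit, loglik=-100.0, n_params=3, n_obs=20)
        aicc, bic, m2ll = information_criteria(fake)
        assert m2ll == 200.0
        assert aicc == pytest.approx(207.5)
        assert bic == pytest.approx(200.0 + 3 * math.log(20))

    def test_aicc_approaches_aic(self, toy_counts):
        fit = SterilityModel(toy_counts, ModelSpec(family="poisson")).fit()
        fake = dataclasses.replace(fit, loglik=-100.0, n_params=3, n_obs=10**7)
        assert fake.aicc - fake.aic < 1e-5

    def test_aicc_missing_when_n_too_small(self, toy_counts):
        fit = SterilityModel(toy_counts, ModelSpec(family="poisson")).fit()
        fake = dataclasses.replace(fit, n_params=12, n_obs=12)
        with pytest.warns(UserWarning):
            assert math.isnan(fake.aicc)

    def test_equal_p_ranking_consistent(self):
        d = zi_dataset([0.4, 0.4], [3.0, 12.0], heads=25, seed=3)
        f_logit = SterilityModel(
            d, ModelSpec(family="hnb", inflation="single")).fit()
        f_zinb = SterilityModel(
            d, ModelSpec(family="zinb", inflation="single")).fit()
        assert f_logit.n_params == f_zinb.n_params
        assert (f_logit.minus2ll < f_zinb.minus2ll) == (f_logit.aicc < f_zinb.aicc)


class TestPearsonOverdispersion:
    def test_poisson_on_poisson_near_one(self):
        rng = np.random.default_rng(5)
        rows = [("s", "g1", "B1", f"H{i}", int(y)) for i, y in
                enumerate(rng.poisson(6.0, size=3000))]
        fit = SterilityModel(make_df(rows), ModelSpec(family="poisson")).fit()
        assert pearson_overdispersion(fit) == pytest.approx(1.0, abs=0.15)

    def test_poisson_on_nb_detects_overdispersion(self):
        # NB(lam=5, k=1): Pearson ratio -> 1 + lam/k = 6
        d = zi_dataset([0.0], [5.0], k=1.0, heads=1500, seed=7)
        fit = SterilityModel(d, ModelSpec(family="poisson")).fit()
        assert pearson_overdispersion(fit) == pytest.approx(6.0, rel=0.25)

    def test_saturated_fit_gives_zero(self):
        rows = [("s", f"g{i}", "B1", "H1", y) for i, y in enumerate([3, 8, 1])]
        with pytest.warns(UserWarning):  # 1 obs per genotype
            fit = SterilityModel(make_df(rows), ModelSpec(family="poisson")).fit()
        assert pearson_overdispersion(fit) == pytest.approx(0.0, abs=1e-6)
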