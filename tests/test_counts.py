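"""Count-model operations: genotype estimates and their structural
identities, inflation probabilities, the delta method, model comparison."""

import math

import numpy as np
import pytest

from sterilecount import (
    ModelSpec,
    SterilityModel,
    compare_models,
    delta_method_se,
    genotype_count_means,
    inflation_probabilities,
    marginal_genotype_means,
)
from sterilecount.counts import datascale_wald_intervals, fit_family
from sterilecount.distributions import TransformSpec

from conftest import make_df, zi_dataset


class TestDeltaMethod:
    @pytest.mark.parametrize(
        "g, x, se, expected",
        [
            (math.exp, 0.0, 0.1, 0.1),                     # g'(0) = 1
            (lambda x: x * x, 2.0, 0.5, 2.0),              # |2x| se
            (TransformSpec("sqrt_three_eighths").inverse, 2.0, 0.1, 0.4),  # g = x^2 - 3/8
        ],
    )
    def test_values(self, g, x, se, expected):
        assert delta_method_se(g, x, se) == pytest.approx(expected, rel=1e-4)

    def test_zero_derivative(self):
        assert delta_method_se(lambda x: 7.0, 1.3, 0.5) == 0.0


class TestGenotypeMeans:
    def test_log_link_estimate_is_exp_alpha_exactly(self):
        d = zi_dataset([0.0, 0.0], [4.0, 9.0], heads=25, seed=2)
        fit = fit_family(d, ModelSpec(family="negbin"))
        for e, a in zip(genotype_count_means(fit), fit.alpha().to_numpy()):
            assert e.estimate == math.exp(a)
            assert e.ci_low <= e.estimate <= e.ci_high  # inverse link preserves order

    def test_intercept_zero_linear_predictor_gives_mean_one(self):
        # with all counts 1, the Poisson log-link genotype effect is ~0
        rows = [("s", "g1", "B1", f"H{i}", 1) for i in range(30)]
        fit = fit_family(make_df(rows), ModelSpec(family="poisson"))
        est = genotype_count_means(fit)[0]
        assert est.estimate == pytest.approx(1.0, abs=1e-6)

    def test_hurdle_zero_probability_equals_pi_exactly(self):
        """Structural hurdle identity: fitted Pr(y=0|genotype) = pi_hat =
        the observed per-genotype zero fraction."""
        d = zi_dataset([0.4, 0.25], [5.0, 12.0], heads=30, seed=11)
        fit = fit_family(d, ModelSpec(family="hnb", inflation="per_genotype"))
        zero_frac = d.df.assign(z=d.df.seed_count == 0).groupby("genotype")["z"].mean()
        for est in inflation_probabilities(fit):
            assert est.pi == pytest.approx(zero_frac[est.genotype], abs=2e-3)

    def test_zinb_on_pure_nb_drives_pi_to_zero(self):
        d = zi_dataset([0.0], [6.0], k=2.0, heads=200, seed=8)
        fit = fit_family(d, ModelSpec(family="zinb", inflation="single"))
        (est,) = inflation_probabilities(fit)
        assert est.genotype == "overall"
        assert est.pi < 0.06
        assert "boundary_zero" in est.flags or est.ci_low < 0.01

    def test_single_pi_labelled_overall(self):
        d = zi_dataset([0.4, 0.4], [4.0, 8.0], heads=20, seed=5)
        fit = fit_family(d, ModelSpec(family="zinb", inflation="single"))
        ests = inflation_probabilities(fit)
        assert [e.genotype for e in ests] == ["overall"]

    def test_pi_half_at_logit_zero(self):
        from scipy.special import expit

        assert expit(0.0) == 0.5  # the mapping used for reporting pi

    def test_log_plus_one_backtransform_bounded_below(self):
        d = zi_dataset([0.6, 0.5], [1.2, 2.0], heads=10, seed=4)
        fit = fit_family(d, ModelSpec(family="gaussian", transform="log_plus_one"))
        for e in genotype_count_means(fit):
            assert e.estimate >= -1.0
            assert e.ci_low >= -1.0

    def test_negative_backtransform_flagged_nonsensical(self):
        # mostly-zero data: the lower CI bound back-transforms below zero
        rows = [("s", "g1", "B1", f"H{i}", 0) for i in range(8)]
        rows += [("s", "g1", "B2", f"H{i}", 1 if i == 0 else 0) for i in range(8)]
        fit = fit_family(make_df(rows), ModelSpec(family="gaussian", transform="log_plus_one"))
        (e,) = genotype_count_means(fit)
        assert e.ci_low < 0
        assert "nonsensical_negative_count" in e.flags

    def test_marginal_mean_consistency_zinb(self):
        """ZINB model-implied mean (1-pi) lambda matches the sample mean."""
        d = zi_dataset([0.4], [6.0], k=2.0, heads=400, seed=19)
        fit = fit_family(d, ModelSpec(family="zinb", inflation="single"))
        (e,) = marginal_genotype_means(fit)
        ybar = d.df["seed_count"].mean()
        assert e.estimate == pytest.approx(ybar, rel=0.05)

    def test_datascale_wald_symmetric(self):
        d = zi_dataset([0.3, 0.4], [4.0, 9.0], heads=25, seed=3)
        fit = fit_family(d, ModelSpec(family="zinb", inflation="per_genotype"))
        for est, lo, hi in datascale_wald_intervals(fit, estimand="component"):
            assert hi - est == pytest.approx(est - lo, rel=1e-9)

    def test_non_converged_fit_refused(self):
        d = zi_dataset([0.3], [4.0], heads=20, seed=3)
        fit = fit_family(d, ModelSpec(family="negbin"))
        import dataclasses

        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            genotype_count_means(bad)


class TestCompareModels:
    def test_negbin_beats_poisson_on_overdispersed_data(self):
        d = zi_dataset([0.45, 0.35], [6.0, 14.0], k=1.0, heads=30, seed=6)
        comp = compare_models(
            d, [ModelSpec(family="poisson"), ModelSpec(family="negbin")]
        )
        t = comp.table.set_index("model")
        assert t.loc["negbin", "AICc"] < t.loc["poisson", "AICc"]
        assert t.loc["poisson", "chi2_df"] > 2.0  # overdispersion visible
        assert abs(t.loc["negbin", "chi2_df"] - 1.0) < 0.75

    def test_identical_specs_identical_rows(self):
        d = zi_dataset([0.3], [5.0], heads=25, seed=9)
        comp = compare_models(d, [ModelSpec(family="poisson"), ModelSpec(family="poisson")])
        a, b = comp.table.iloc[0], comp.table.iloc[1]
        assert a["AICc"] == b["AICc"] and a["minus2LL"] == b["minus2LL"]

    def test_transformed_rows_marked_not_comparable(self):
        d = zi_dataset([0.4, 0.3], [3.0, 8.0], heads=20, seed=10)
        comp = compare_models(
            d,
            [ModelSpec(family="gaussian", transform="log_plus_one"),
             ModelSpec(family="zinb", inflation="single")],
        )
        t = comp.table.set_index("model")
        assert not t.loc["log-transformed", "comparable"]
        assert t.loc["zinb_single", "comparable"]

    def test_needs_two_specs(self):
        d = zi_dataset([0.3], [5.0], heads=10, seed=1)
        with pytest.raises(ValueError):
            compare_models(d, [ModelSpec(family="poisson")])
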