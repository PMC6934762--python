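"""Crossing-block generator: design structure, published parameter tables,
moment consistency, and reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest

from sterilecount import (
    GeneratorConfig,
    generate_crossing_block,
    paper_like_config,
    summarize,
)
from sterilecount.distributions import base_pmf
from sterilecount.generate import ConfigurationError


def simple_config(**kw):
    labels = kw.pop("labels", [f"g{i}" for i in range(3)])
    base = dict(
        genotype_labels=labels,
        pi_by_genotype={g: 0.3 for g in labels},
        lambda_by_genotype={g: 5.0 for g in labels},
        nb_dispersion=2.0,
        n_blocks=4,
        heads_per_plot=5,
        seed=0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerator:
    def test_degenerate_mixture_all_zero(self):
        labels = [f"g{i}" for i in range(3)]
        cfg = simple_config(pi_by_genotype={g: 1.0 for g in labels})
        data = generate_crossing_block(cfg)
        assert (data.df["seed_count"] == 0).all()

    def test_record_count_without_bag_loss(self):
        labels = [f"g{i}" for i in range(27)]
        cfg = simple_config(
            labels=labels,
            pi_by_genotype={g: 0.3 for g in labels},
            lambda_by_genotype={g: 5.0 for g in labels},
        )
        assert len(generate_crossing_block(cfg)) == 27 * 4 * 5

    def test_zero_proportion_matches_closed_form(self):
        # Pr(0) = pi + (1-pi) f(0) for the zero-inflated process
        pi, lam, k = 0.38, 5.0, 2.0
        cfg = simple_config(
            labels=["g"],
            pi_by_genotype={"g": pi},
            lambda_by_genotype={"g": lam},
            nb_dispersion=k,
            n_blocks=4,
            heads_per_plot=2500,
            seed=42,
        )
        data = generate_crossing_block(cfg)
        p0 = pi + (1 - pi) * float(base_pmf(0, lam, k))
        phat = float((data.df["seed_count"] == 0).mean())
        se = math.sqrt(p0 * (1 - p0) / len(data))
        assert phat >= pi - 3 * se
        assert abs(phat - p0) <= 3 * se

    def test_hurdle_zero_proportion_is_pi(self):
        pi = 0.45
        cfg = simple_config(
            labels=["g"],
            pi_by_genotype={"g": pi},
            lambda_by_genotype={"g": 4.0},
            process="hurdle",
            heads_per_plot=2500,
            seed=9,
        )
        data = generate_crossing_block(cfg)
        phat = float((data.df["seed_count"] == 0).mean())
        assert abs(phat - pi) <= 3 * math.sqrt(pi * (1 - pi) / len(data))
        positives = data.df.loc[data.df["seed_count"] > 0, "seed_count"]
        assert positives.min() >= 1

    def test_mean_consistency_without_random_effects(self):
        lam = 7.0
        cfg = simple_config(
            labels=["g"],
            pi_by_genotype={"g": 0.0},
            lambda_by_genotype={"g": lam},
            nb_dispersion=1.5,
            heads_per_plot=5000,
            seed=3,
        )
        data = generate_crossing_block(cfg)
        se = math.sqrt((lam + lam**2 / 1.5) / len(data))
        assert abs(data.df["seed_count"].mean() - lam) <= 3 * se

    def test_reproducibility_and_seed_sensitivity(self):
        cfg = simple_config(seed=123)
        d1 = generate_crossing_block(cfg)
        d2 = generate_crossing_block(cfg)
        pd.testing.assert_frame_equal(d1.df, d2.df)
        d3 = generate_crossing_block(simple_config(seed=124))
        assert not d1.df.equals(d3.df)

    @pytest.mark.parametrize(
        "bad",
        [
            {"pi_by_genotype": {"g0": 1.2, "g1": 0.3, "g2": 0.3}},
            {"lambda_by_genotype": {"g0": -1.0, "g1": 5.0, "g2": 5.0}},
            {"nb_dispersion": 0.0},
            {"bag_loss_prob": float("nan")},
            {"labels": []},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            simple_config(**bad)

    def test_config_roundtrip_json_yaml(self, tmp_path):
        cfg = simple_config(seed=5)
        for name in ("c.json", "c.yaml"):
            p = tmp_path / name
            cfg.save(p)
            assert GeneratorConfig.load(p) == cfg


class TestPaperLikeConfig:
    def test_published_2015_parameters(self):
        cfg = paper_like_config(2015)
        assert cfg.lambda_by_genotype["TX12M4063"] == 25.749
        assert cfg.pi_by_genotype["TX12M4065"] == 0.119
        assert "NE10478-1" in cfg.genotype_labels
        assert len(cfg.genotype_labels) == 26  # 'Harry' entered in 2016 only

    def test_2015_expected_sample_size(self):
        cfg = paper_like_config(2015)
        n_design = len(cfg.genotype_labels) * cfg.n_blocks * cfg.heads_per_plot
        assert n_design * (1 - cfg.bag_loss_prob) == pytest.approx(371.0)

    def test_2016_zero_proportion_calibration(self):
        cfg = paper_like_config(2016, seed=21)
        cfg2 = type(cfg)(**{**cfg.to_dict(), "heads_per_plot": 400, "bag_loss_prob": 0.0})
        data = generate_crossing_block(cfg2)
        phat = float((data.df["seed_count"] == 0).mean())
        se = math.sqrt(0.64 * 0.36 / len(data))
        assert abs(phat - 0.64) <= 3 * se

    def test_2016_mean_calibration(self):
        cfg = paper_like_config(2016, seed=4)
        cfg2 = type(cfg)(**{**cfg.to_dict(), "heads_per_plot": 400, "bag_loss_prob": 0.0})
        s = summarize(generate_crossing_block(cfg2), by_year=False)
        se = math.sqrt(35.8 / s.n_obs)
        assert abs(s.mean - 2.6) <= 3 * se

    def test_unknown_year(self):
        with pytest.raises(ConfigurationError):
            paper_like_config(2014)

    def test_metadata_records_seed(self):
        data = generate_crossing_block(paper_like_config(2015, seed=77))
        assert data.metadata["seed"] == 77
        assert data.metadata["synthetic"] is True
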