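"""Study-level convenience configurations.

The coverage simulation is routinely run on a lambda-stratified subset of
the published 2015 genotype parameters: genotypes are ordered by their count
mean and picked at evenly spaced ranks, so the subset spans the full range
(from LCH13NEDH-11-24 at ~2.6 seeds to TX12M4063 at ~25.7) while keeping
runtimes down.  The subset is a deterministic function of (year,
n_genotypes), never of any fitted result.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .generate import GeneratorConfig, paper_like_config

__all__ = ["coverage_generator_subset"]


def coverage_generator_subset(
    year="2015",
    n_genotypes: int | None = 8,
    heads_per_plot: int = 5,
    n_blocks: int = 4,
    seed: int = 0,
) -> GeneratorConfig:
    """Generator for the coverage study: published parameters, no bag loss.

    ``n_genotypes=None`` keeps all genotypes.  Bag loss is disabled (the
    simulated experiments are balanced: ``n_blocks * heads_per_plot`` heads
    per genotype) and random-effect SDs are zero, matching an i.i.d.
    Bernoulli + negative-binomial simulation process.
    """
    base = paper_like_config(year, seed=seed)
    genotypes = base.genotype_labels
    if n_genotypes is not None and n_genotypes < len(genotypes):
        lams = np.array([base.lambda_by_genotype[g] for g in genotypes])
        order = np.argsort(lams, kind="stable")
        ranks = np.unique(np.round(np.linspace(0, len(genotypes) - 1, n_genotypes)).astype(int))
        genotypes = [genotypes[i] for i in order[ranks]]
    return dataclasses.replace(
        base,
        genotype_labels=list(genotypes),
        pi_by_genotype={g: base.pi_by_genotype[g] for g in genotypes},
        lambda_by_genotype={g: base.lambda_by_genotype[g] for g in genotypes},
        n_blocks=n_blocks,
        heads_per_plot=heads_per_plot,
        bag_loss_prob=0.0,
        block_sd=0.0,
        wholeplot_sd=0.0,
        process="zero_inflated",
        seed=seed,
    )
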