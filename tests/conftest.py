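"""Shared fixtures and simulation helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from sterilecount import GeneratorConfig, SeedCountDataset, generate_crossing_block


def make_df(rows):
    """Long-format frame from (year, genotype, block, head, seed_count) rows."""
    return pd.DataFrame(rows, columns=["year", "genotype", "block", "head", "seed_count"])


def binary_df(probs, block_sd=0.25, n_blocks=4, heads=5, seed=0):
    """Bernoulli crossing-block data with a normal block effect on the logit
    scale; used for threshold-model operating-characteristic simulations."""
    rng = np.random.default_rng(seed)
    be = rng.normal(0.0, block_sd, n_blocks) if block_sd > 0 else np.zeros(n_blocks)
    rows = []
    for gi, p in enumerate(probs):
        eta0 = logit(p)
        for b in range(n_blocks):
            pr = expit(eta0 + be[b])
            y = (rng.random(heads) < pr).astype(int)
            for h in range(heads):
                rows.append(("s", f"g{gi:02d}", f"B{b}", f"H{h}", int(y[h])))
    df = make_df(rows)
    return df.rename(columns={"seed_count": "success"})


def zi_dataset(pis, lams, k=2.0, n_blocks=4, heads=5, seed=0, process="zero_inflated"):
    """Zero-inflated (or hurdle) NB crossing-block dataset, iid given genotype."""
    labels = [f"g{i}" for i in range(len(pis))]
    cfg = GeneratorConfig(
        genotype_labels=labels,
        pi_by_genotype=dict(zip(labels, pis)),
        lambda_by_genotype=dict(zip(labels, lams)),
        nb_dispersion=k,
        n_blocks=n_blocks,
        heads_per_plot=heads,
        process=process,
        seed=seed,
    )
    return generate_crossing_block(cfg)


@pytest.fixture
def toy_counts():
    """Two genotypes x two blocks, 12 observations of hand-set counts."""
    rows = []
    counts = {("g1", "B1"): [0, 3, 7], ("g1", "B2"): [1, 0, 2],
              ("g2", "B1"): [10, 4, 0], ("g2", "B2"): [5, 8, 12]}
    for (g, b), ys in counts.items():
        for i, y in enumerate(ys):
            rows.append(("2015", g, b, f"H{i}", y))
    return SeedCountDataset(make_df(rows))
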