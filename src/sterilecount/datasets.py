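"""Seed-count datasets: the long-format container, CSV I/O, and summaries.

A crossing-block sterility assay records, for every bagged wheat head, the
number of selfed seeds that formed despite the chemical hybridizing agent.
Records carry ``year``, ``genotype``, ``block`` and ``head`` identifiers plus
the nonnegative integer ``seed_count``; (year, genotype, block, head) is a
unique key.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["year", "genotype", "block", "head", "seed_count"]


class ParseError(ValueError):
    """Raised when a seed-count CSV violates the format contract."""


@dataclasses.dataclass
class SeedCountDataset:
    """Long-format seed-count observations with design metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``year, genotype, block, head, seed_count``.
    metadata : dict
        Provenance notes; synthetic datasets record their generator seed here.
    """

    df: pd.DataFrame
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParseError(f"missing required column(s): {missing}")
        counts = self.df["seed_count"]
        bad = counts.isna() | (counts < 0) | (counts != counts.astype("int64", errors="ignore"))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"seed_count must be a nonnegative integer; offending row {row}: "
                f"{self.df.iloc[row].to_dict()}"
            )
        self.df = self.df.copy()
        self.df["seed_count"] = self.df["seed_count"].astype("int64")
        key = self.df[["year", "genotype", "block", "head"]].astype(str)
        if key.duplicated().any():
            row = int(np.flatnonzero(key.duplicated().to_numpy())[0])
            raise ParseError(
                f"duplicate (year, genotype, block, head) key at row {row}: "
                f"{self.df.iloc[row].to_dict()}"
            )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self):
        """Records as a list of (year, genotype, block, head, seed_count)."""
        return list(self.df[REQUIRED_COLUMNS].itertuples(index=False, name=None))

    @property
    def genotypes(self):
        return sorted(self.df["genotype"].astype(str).unique())

    @property
    def blocks(self):
        return sorted(self.df["block"].astype(str).unique())

    def subset_year(self, year) -> "SeedCountDataset":
        sub = self.df[self.df["year"].astype(str) == str(year)].reset_index(drop=True)
        return SeedCountDataset(sub, dict(self.metadata))

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df[REQUIRED_COLUMNS].to_csv(path, index=False)


def read_counts(path) -> SeedCountDataset:
    """Read a seed-count CSV (header ``year,genotype,block,head,seed_count``).

    Rows with a missing seed_count are dropped with a logged warning; any
    negative or non-integer count raises :class:`ParseError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {missing}")
    na = df["seed_count"].isna()
    if na.any():
        logger.warning(
            "%s: dropping %d row(s) with missing seed_count", path, int(na.sum())
        )
        df = df[~na].reset_index(drop=True)
    ints = pd.to_numeric(df["seed_count"], errors="coerce")
    bad = ints.isna() | (ints < 0) | (ints % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: seed_count must be a nonnegative integer at data row {row}: "
            f"{df.iloc[row].to_dict()}"
        )
    df["seed_count"] = ints.astype("int64")
    return SeedCountDataset(df, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of raw seed counts for one group (e.g. a year).

    ``skewness`` is the adjusted Fisher-Pearson sample coefficient
    ``g1 * sqrt(n(n-1))/(n-2)``; it is reported as NaN when undefined
    (n < 3 or zero variance), as is anything else undefined for the group.
    """

    n_obs: int
    mean: float
    variance: float
    sd: float
    prop_zero: float
    skewness: float
    median: float
    mode: int
    min: int
    max: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _summarize_counts(counts: np.ndarray) -> SummaryStats:
    if counts.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = int(counts.size)
    var = float(np.var(counts, ddof=1)) if n > 1 else float("nan")
    if n >= 3 and var > 0:
        skew = float(sps.skew(counts, bias=False))
    else:
        skew = float("nan")
    values, freq = np.unique(counts, return_counts=True)
    mode = int(values[np.argmax(freq)])  # np.unique sorts: smallest on ties
    return SummaryStats(
        n_obs=n,
        mean=float(np.mean(counts)),
        variance=var,
        sd=float(np.sqrt(var)) if var == var else float("nan"),
        prop_zero=float(np.mean(counts == 0)),
        skewness=skew,
        median=float(np.median(counts)),
        mode=mode,
        min=int(counts.min()),
        max=int(counts.max()),
    )


def summarize(data: SeedCountDataset, by_year: bool = True):
    """Descriptive statistics of the raw counts.

    Returns a dict ``{year: SummaryStats}`` when ``by_year`` is true, else a
    single :class:`SummaryStats` over all records.
    """
    if by_year:
        out = {}
        for year, grp in data.df.groupby(data.df["year"].astype(str), sort=True):
            out[year] = _summarize_counts(grp["seed_count"].to_numpy())
        if not out:
            raise ValueError("cannot summarize an empty dataset")
        return out
    return _summarize_counts(data.df["seed_count"].to_numpy())


def summary_table(data: SeedCountDataset) -> pd.DataFrame:
    """Per-year summary statistics as a table (one column per year)."""
    stats = summarize(data, by_year=True)
    tab = pd.DataFrame({year: s.to_dict() for year, s in stats.items()})
    tab.index.name = "statistic"
    return tab


def plot_histogram(data: SeedCountDataset, path) -> None:
    """Export per-year seed-count histograms (optional diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = sorted(data.df["year"].astype(str).unique())
    fig, axes = plt.subplots(1, len(years), figsize=(4 * len(years), 3), squeeze=False)
    for ax, year in zip(axes[0], years):
        counts = data.df[data.df["year"].astype(str) == year]["seed_count"]
        ax.hist(counts, bins=range(0, int(counts.max()) + 2))
        ax.set_title(str(year))
        ax.set_xlabel("seeds per head")
        ax.set_ylabel("heads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
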