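"""Count-based probability estimators and the Welch t-test.

Phenotype probabilities are estimated per experiment as count/total and
summarized across experiments by their mean and standard error
(SD/√n).  Group comparisons use the unpaired two-sample t-test assuming
unequal variances (Welch), with Welch–Satterthwaite degrees of freedom
and a two-sided p-value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = ["CountTable", "TestResult", "category_probabilities",
           "welch_t_test", "SIZE_CLASSES"]

#: GUV size classes by diameter, µm.
SIZE_CLASSES = {"small": (7.0, 12.0), "medium": (12.0, 16.0),
                "large": (16.0, np.inf)}


@dataclass
class CountTable:
    """Per-experiment category counts in long format.

    Backed by a DataFrame with columns ``experiment, category, count,
    total``; ``total`` is the number of captured units (e.g. GUVs of one
    size class) in that experiment.
    """

    df: pd.DataFrame

    REQUIRED = ("experiment", "category", "count", "total")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.df["count"] > self.df["total"]).any():
            raise ValueError("category counts cannot exceed totals")

    @classmethod
    def from_records(cls, rows) -> "CountTable":
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    @classmethod
    def read_csv(cls, path) -> "CountTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def experiments(self) -> list:
        return list(dict.fromkeys(self.df["experiment"]))

    @property
    def categories(self) -> list:
        return list(dict.fromkeys(self.df["category"]))


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def category_probabilities(table: CountTable) -> pd.DataFrame:
    """Per-category probability mean ± SEM across experiments.

    Each experiment contributes p = count/total; the summary is the mean
    and SEM = SD/√n over the n experiments.  A single experiment yields
    SEM 0 with a warning; a zero total raises, naming the experiment.
    """
    df = table.df
    zero = df.loc[df["total"] == 0, "experiment"]
    if len(zero):
        raise ValueError(f"experiment {zero.iloc[0]!r} has zero total")
    df = df.assign(p=df["count"] / df["total"])
    out = []
    for cat, g in df.groupby("category", sort=False):
        probs = g["p"].to_numpy(dtype=float)
        n = len(probs)
        if n == 1:
            warnings.warn(f"category {cat!r}: single experiment, SEM "
                          "reported as 0", stacklevel=2)
            sem = 0.0
        else:
            sem = probs.std(ddof=1) / np.sqrt(n)
        out.append({"category": cat, "mean": probs.mean(), "sem": sem,
                    "n_experiments": n,
                    "per_experiment": probs})
    return pd.DataFrame(out)


def welch_t_test(group_a, group_b) -> TestResult:
    """Welch's unequal-variance t-test, two-sided.

    Requires at least two values per group and a nonzero pooled
    variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of difference
            return TestResult(0.0, float(len(a) + len(b) - 2), 1.0)
        raise ValueError("both groups have zero variance; "
                         "the Welch statistic is undefined")
    res = _sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df),
                      float(res.pvalue))
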