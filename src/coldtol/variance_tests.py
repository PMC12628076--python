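"""Variance-equality and normality screens for well-median lengths.

Environmental stress can inflate phenotypic variance (de-canalisation), so
the pipeline compares the spread of well medians between cold-treated and
control animals.  Because control lengths are typically left-skewed, the
comparison uses the Brown–Forsythe form of Levene's test — a one-way ANOVA
on absolute deviations from the *group medians* — which keeps its nominal
size under skew.  The Shapiro–Wilk screen that motivates this choice is
also exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LeveneResult:
    F: float
    df1: int
    df2: int
    p: float


def brown_forsythe(*groups: Sequence[float]) -> LeveneResult:
    """Median-centred Levene test for equality of variances.

    Computes z_ij = |x_ij − median(group_i)| and returns the one-way
    fixed-effects ANOVA F on the z values, with df1 = k − 1 and
    df2 = N − k.  A group with identical values legally contributes zero
    deviations; if every group is a single repeated value the F statistic
    is undefined and a ValueError is raised.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    zs = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("each group needs at least two observations")
        zs.append(np.abs(arr - np.median(arr)))

    k = len(zs)
    N = sum(z.size for z in zs)
    grand = np.concatenate(zs).mean()
    ss_between = sum(z.size * (z.mean() - grand) ** 2 for z in zs)
    ss_within = sum(((z - z.mean()) ** 2).sum() for z in zs)
    df1, df2 = k - 1, N - k
    if all((z == 0).all() for z in zs):
        raise ValueError("all groups are degenerate; F undefined")
    if ss_between == 0:
        # equal mean deviations across groups: no evidence of unequal spread
        return LeveneResult(F=0.0, df1=df1, df2=df2, p=1.0)
    if ss_within == 0:
        return LeveneResult(F=np.inf, df1=df1, df2=df2, p=0.0)
    F = (ss_between / df1) / (ss_within / df2)
    return LeveneResult(F=float(F), df1=df1, df2=df2, p=float(stats.f.sf(F, df1, df2)))


def variance_test_by_treatment(table: pd.DataFrame) -> LeveneResult:
    """Brown–Forsythe on the post-QC well medians, control vs cold.

    All surviving well medians are pooled across strains and plate designs
    into exactly two groups split by treatment, so df1 = 1 and
    df2 = (total retained wells) − 2.
    """
    groups = [
        g["median_length_um"].to_numpy(float)
        for _, g in table.groupby("treatment", sort=True)
    ]
    if len(groups) != 2:
        raise ValueError("expected exactly two treatment levels")
    return brown_forsythe(*groups)


def normality_screen(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p for a sample of well medians (3 ≤ n ≤ 5000)."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("constant input: zero variance")
    w, p = stats.shapiro(arr)
    return float(w), float(p)
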