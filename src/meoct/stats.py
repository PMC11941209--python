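"""Group summaries and unpaired two-sample t-tests.

Clinical middle-ear OCT studies report intensity ratios per diagnostic group
as mean ± standard error (SE) and compare groups with an unpaired Student's
t-test at alpha = 0.05.  Published tables rarely include raw per-ear values,
so this module supports two entry points: tests computed directly from raw
ratio samples, and tests reconstructed exactly from printed (n, mean, SE)
summaries.  The reconstruction uses the identity s^2 = SE^2 * n, which
recovers the sample variance without loss, so a from-summary test on a
group's own summary equals the from-samples test on the raw values.

The pooled (equal-variance) Student's t is the default variant; Welch's
unequal-variance test is available via ``variant="welch"``.  All p-values are
two-tailed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "ttest_from_summary",
    "ttest_from_samples",
    "compare_all",
    "compare_all_from_summaries",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean, and standard error of the mean.

    ``se`` is the sample standard deviation (n-1 denominator) divided by
    sqrt(n).  For a singleton group the SE is undefined; it is reported as
    0.0 with ``se_defined=False``, matching how an n = 1 diagnosis is
    reported descriptively without an error bar.
    """

    label: str
    n: int
    mean: float
    se: float
    se_defined: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.se < 0:
            raise ValueError(f"group {self.label!r}: se must be >= 0, got {self.se}")

    @property
    def sample_var(self) -> float:
        """Sample variance reconstructed from the SE: s^2 = se^2 * n."""
        return self.se**2 * self.n


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed unpaired t-test outcome."""

    t: float
    df: float
    p: float
    variant: str
    group_a: str = ""
    group_b: str = ""

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def summarize(values: Iterable[float], label: str = "") -> GroupSummary:
    """Summarize a group of ratios as (n, mean, SE)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        return GroupSummary(label=label, n=1, mean=mean, se=0.0, se_defined=False)
    se = float(arr.std(ddof=1) / math.sqrt(n))
    return GroupSummary(label=label, n=n, mean=mean, se=se)


def ttest_from_summary(
    g1: GroupSummary, g2: GroupSummary, variant: str = "pooled"
) -> TTestResult:
    """Unpaired two-sample t-test from (n, mean, SE) summaries.

    Reconstructs each group's sample variance as s^2 = se^2 * n.  The pooled
    variant uses s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2) with
    df = n1 + n2 - 2; the Welch variant uses the Welch-Satterthwaite df.
    """
    for g in (g1, g2):
        if g.n < 2:
            raise ValueError(f"group {g.label!r}: t-test needs n >= 2, got n = {g.n}")
        if g.se <= 0:
            raise ValueError(f"group {g.label!r}: t-test needs se > 0")
    v1, v2 = g1.sample_var, g2.sample_var
    n1, n2 = g1.n, g2.n
    diff = g1.mean - g2.mean
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        se2 = v1 / n1 + v2 / n2
        t = diff / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(
        t=float(t), df=float(df), p=p, variant=variant,
        group_a=g1.label, group_b=g2.label,
    )


def ttest_from_samples(
    x1: Sequence[float], x2: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Unpaired t-test from raw samples; equals the from-summary test applied
    to the samples' own summaries."""
    s1 = summarize(x1, "sample_1")
    s2 = summarize(x2, "sample_2")
    if s1.se == 0 and s2.se == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    return ttest_from_summary(s1, s2, variant=variant)


def compare_all_from_summaries(
    summaries: Sequence[GroupSummary], variant: str = "pooled", alpha: float = ALPHA
) -> pd.DataFrame:
    """All pairwise unpaired t-tests among groups with n >= 2.

    Groups with n = 1 are excluded from testing (they appear only
    descriptively in group summaries, as is conventional for a singleton
    diagnosis).  Returns a tidy table with a significance flag at ``alpha``.
    No multiple-testing correction is applied; the number of comparisons is
    carried in the table so readers can judge multiplicity.
    """
    testable = [g for g in summaries if g.n >= 2 and g.se > 0]
    rows = []
    pairs = list(itertools.combinations(testable, 2))
    for ga, gb in pairs:
        res = ttest_from_summary(ga, gb, variant=variant)
        rows.append(
            {
                "group_a": ga.label,
                "group_b": gb.label,
                "n_a": ga.n,
                "n_b": gb.n,
                "mean_a": ga.mean,
                "mean_b": gb.mean,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.p < alpha,
                "variant": variant,
                "n_comparisons": len(pairs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "n_a", "n_b", "mean_a", "mean_b",
            "t", "df", "p", "significant", "variant", "n_comparisons",
        ],
    )


def compare_all(
    ratios: pd.DataFrame,
    group_col: str = "class_label",
    value_col: str = "ratio",
    variant: str = "pooled",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pairwise tests over a tidy ratios table (one row per ear)."""
    summaries = [
        summarize(sub[value_col].to_numpy(), label=str(name))
        for name, sub in ratios.groupby(group_col, sort=True)
    ]
    return compare_all_from_summaries(summaries, variant=variant, alpha=alpha)
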