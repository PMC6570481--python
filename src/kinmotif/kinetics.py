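"""Initial-rate estimation for peptide kinase assays.

A kinase assay samples radiolabel incorporation (scintillation counts per
minute, CPM) at several timepoints in the linear regime; the
phosphorylation rate is the slope of the ordinary-least-squares regression
of counts on time.  Rates are compared between substrates at the level of
per-replicate fitted slopes: a two-sample t-test for two groups, one-way
ANOVA with Tukey HSD post-hoc pairwise comparisons for more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InputError


@dataclass
class TimeCourse:
    """Counts (CPM) versus time (minutes) for one reaction replicate."""

    label: str
    replicate_id: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise InputError(
                f"times and counts differ in length ({len(self.times)} vs {len(self.counts)})"
            )
        if len(self.times) < 2:
            raise InputError("a time course needs at least 2 points")
        if (self.times < 0).any():
            raise InputError("times must be nonnegative")


@dataclass
class RateEstimate:
    """OLS fit of counts on time: the slope is the phosphorylation rate."""

    label: str
    replicate_id: str
    slope: float  # CPM / min
    intercept: float  # CPM
    slope_se: float
    r_squared: float
    n_points: int


def fit_rate(tc: TimeCourse) -> RateEstimate:
    """Ordinary least squares of counts on time; slope = phosphorylation rate."""
    if len(np.unique(tc.times)) < 2:
        raise DegenerateDataError(f"all timepoints identical for {tc.label}/{tc.replicate_id}")
    res = stats.linregress(tc.times, tc.counts)
    return RateEstimate(
        label=tc.label,
        replicate_id=tc.replicate_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=len(tc.times),
    )


def compare_rates(
    groups: dict[str, list[RateEstimate]], paired: bool = False
) -> pd.DataFrame:
    """Compare fitted slopes between substrate groups.

    Two groups: two-sample t-test on the per-replicate slopes (``paired=True``
    switches to a paired test).  More than two: one-way ANOVA, then Tukey HSD
    for the pairwise rows.  Each row reports the pair, mean slopes, the slope
    ratio as effect size, the test statistic and p-value.  Groups with fewer
    than 2 replicates yield descriptive rows (NaN statistics) with a warning.
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups to compare")
    slopes = {k: np.array([r.slope for r in v], dtype=float) for k, v in groups.items()}
    for name, s in slopes.items():
        if len(s) == 0:
            raise InputError(f"group {name!r} is empty")
        if len(s) < 2:
            warnings.warn(
                f"group {name!r} has a single replicate; statistics are descriptive only",
                stacklevel=2,
            )
    inferential = all(len(s) >= 2 for s in slopes.values())
    anova_p = np.nan
    if inferential and len(groups) > 2:
        anova_p = float(stats.f_oneway(*slopes.values()).pvalue)

    tukey = None
    if inferential and len(groups) > 2:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        flat = np.concatenate(list(slopes.values()))
        labels = np.concatenate([[k] * len(v) for k, v in slopes.items()])
        if np.all(flat == flat[0]):
            warnings.warn("all slopes identical across groups; comparison is degenerate", stacklevel=2)
        else:
            res = pairwise_tukeyhsd(flat, labels)
            tukey = {
                (str(a), str(b)): (float(md), float(p))
                for (a, b), md, p in zip(_pairs(res), res.meandiffs, res.pvalues)
            }

    rows = []
    for a, b in combinations(slopes, 2):
        sa, sb = slopes[a], slopes[b]
        stat = p = np.nan
        method = "descriptive"
        if inferential:
            if len(groups) == 2:
                if sa.std(ddof=1) == 0 and sb.std(ddof=1) == 0:
                    warnings.warn(
                        "zero within-group variance in both groups; t-test degenerate",
                        stacklevel=2,
                    )
                    stat, p = (0.0, 1.0) if np.mean(sa) == np.mean(sb) else (np.inf, 0.0)
                    method = "t-test (degenerate variance)"
                elif paired:
                    if len(sa) != len(sb):
                        raise InputError("paired t-test requires equal group sizes")
                    t = stats.ttest_rel(sa, sb)
                    stat, p, method = float(t.statistic), float(t.pvalue), "paired t-test"
                else:
                    t = stats.ttest_ind(sa, sb)
                    stat, p, method = float(t.statistic), float(t.pvalue), "t-test"
            else:
                method = "ANOVA + Tukey HSD"
                if tukey is not None:
                    key = (a, b) if (a, b) in tukey else (b, a)
                    stat, p = tukey.get(key, (np.nan, np.nan))
        mean_a, mean_b = float(np.mean(sa)), float(np.mean(sb))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_slope_a": mean_a,
                "mean_slope_b": mean_b,
                "slope_ratio": mean_a / mean_b if mean_b != 0 else np.inf,
                "statistic": stat,
                "p_value": p,
                "anova_p": anova_p,
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def _pairs(res):
    """Ordered group pairs of a statsmodels TukeyHSD result."""
    names = list(res.groupsunique)
    return list(combinations(names, 2))
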