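"""Group-level comparisons: mean +/- SEM, Student's t, drug-response change.

Mirrors the analysis workflow around the pillar measurements: per-
experiment summary values (e.g. maximum pillar displacement per recording)
are aggregated as mean +/- standard error over independent experiments,
conditions are compared with Student's two-sample t-test (* p < 0.05,
** p < 0.01), and drug effects are expressed as the percent decrease of
each experiment's own pre-treatment value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "GroupComparison",
    "summarize_group",
    "compare_groups",
    "normalize_drug_response",
    "daywise_table",
    "significance_tier",
]


@dataclass
class GroupSample:
    """Per-experiment summary values for one condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        if self.n < 2:
            return np.nan
        return float(self.values.std(ddof=1) / np.sqrt(self.n))


@dataclass
class GroupComparison:
    """Two-group comparison: means, SEMs, t, p and significance tier."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    percent_difference: float  # 100 * (mean_b - mean_a) / mean_a
    t: float
    p: float
    tier: str  # "**", "*" or "NS"
    infinite_t: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "label_a", "label_b", "mean_a", "mean_b", "sem_a", "sem_b",
            "n_a", "n_b", "percent_difference", "t", "p", "tier",
        )}


def significance_tier(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def summarize_group(values) -> tuple[float, float, int]:
    """Mean, SEM (sample sd / sqrt(n), NaN at n=1) and n."""
    g = GroupSample("group", values)
    return g.mean, g.sem, g.n


def compare_groups(a: GroupSample, b: GroupSample, *, paired: bool = False,
                   welch: bool = False) -> GroupComparison:
    """Student's two-sample t-test between two condition groups.

    Pooled-variance Student's t by default; Welch's unequal-variance
    variant behind ``welch=True``; ``paired=True`` runs the paired test on
    matched experiments.  Degenerate zero-variance input is resolved
    explicitly: equal means give t=0, p=1; unequal means give an
    infinite-t flag with p=0.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    if paired:
        if a.n != b.n:
            raise ValueError("paired test requires equal group sizes")
        res = sps.ttest_rel(a.values, b.values)
        t, p = float(res.statistic), float(res.pvalue)
        infinite = not np.isfinite(t)
    else:
        var = a.values.var(ddof=1) + b.values.var(ddof=1)
        if var == 0:
            if a.mean == b.mean:
                t, p, infinite = 0.0, 1.0, False
            else:
                t = np.inf if b.mean > a.mean else -np.inf
                p, infinite = 0.0, True
        else:
            res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
            infinite = not np.isfinite(t)
    if infinite:
        p = 0.0
    pct = 100.0 * (b.mean - a.mean) / a.mean if a.mean != 0 else np.nan
    return GroupComparison(
        label_a=a.label, label_b=b.label,
        mean_a=a.mean, mean_b=b.mean,
        sem_a=a.sem, sem_b=b.sem,
        n_a=a.n, n_b=b.n,
        percent_difference=pct,
        t=t, p=p,
        tier=significance_tier(p),
        infinite_t=infinite,
    )


def normalize_drug_response(pre, post, labels=None) -> tuple[np.ndarray, tuple]:
    """Percent decrease of each experiment's value after treatment.

    For matched pre/post values per experiment, computes
    100 * (pre - post) / pre (positive = the drug reduced contraction),
    then summarises across experiments as (mean, SEM, n).  Scale-invariant
    by construction.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be matched per experiment")
    bad = np.flatnonzero(~(pre > 0))
    if bad.size:
        name = labels[bad[0]] if labels is not None else f"index {bad[0]}"
        raise ValueError(f"non-positive pre-treatment baseline in experiment {name}")
    pct = 100.0 * (pre - post) / pre
    return pct, summarize_group(pct)


def daywise_table(table: pd.DataFrame, metric: str,
                  condition_col: str = "condition",
                  day_col: str = "day") -> pd.DataFrame:
    """Day-by-condition aggregation of a tidy per-experiment table.

    Input columns: experiment_id, condition, day, metric, value (tidy,
    one row per experiment-day-metric).  Returns mean, SEM and n per
    (condition, day) plus, where both conditions have n >= 2 on a day,
    the Student's t comparison between them.
    """
    sel = table[table["metric"] == metric]
    rows = []
    for (cond, day), grp in sel.groupby([condition_col, day_col]):
        mean, sem, n = summarize_group(grp["value"].to_numpy())
        rows.append({"condition": cond, "day": day,
                     "mean": mean, "sem": sem, "n": n})
    summary = pd.DataFrame(rows)

    tests = []
    for day, grp in sel.groupby(day_col):
        conds = sorted(grp[condition_col].unique())
        if len(conds) != 2:
            continue
        va = grp.loc[grp[condition_col] == conds[0], "value"].to_numpy()
        vb = grp.loc[grp[condition_col] == conds[1], "value"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            continue  # reported without a test
        cmp_ = compare_groups(GroupSample(str(conds[0]), va),
                              GroupSample(str(conds[1]), vb))
        tests.append({"day": day, "t": cmp_.t, "p": cmp_.p, "tier": cmp_.tier,
                      "percent_difference": cmp_.percent_difference})
    tests_df = pd.DataFrame(tests, columns=["day", "t", "p", "tier",
                                            "percent_difference"])
    return summary.merge(tests_df, on="day", how="left")
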