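"""Group statistics and summaries in the study's reporting conventions.

One-way ANOVA across groups with Tukey HSD (default) or Bonferroni post-hoc
comparisons; significance stars at the conventional cutoffs (* <= 0.05,
** <= 0.01, *** <= 0.001, **** <= 0.0001); boxplot summaries with linearly
interpolated quartiles and Tukey-fence outliers, matching the figures'
boxplot convention (median line, 25th-75th percentile box, outlier dots).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    for cutoff, stars in STAR_LEVELS:
        if p <= cutoff:
            return stars
    return "ns"


@dataclass
class BoxplotSummary:
    median: float
    q25: float
    q75: float
    outliers: list[float]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    stars: str


@dataclass
class GroupComparison:
    metric: str
    groups: list[str]
    n_per_group: dict[str, int]
    f_stat: float
    p_value: float
    posthoc_method: str
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    summaries: dict[str, BoxplotSummary] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": list(self.groups),
            "n_per_group": dict(self.n_per_group),
            "anova_F": self.f_stat,
            "anova_p": self.p_value,
            "posthoc_method": self.posthoc_method,
            "pairwise": [
                {
                    "pair": [c.group_a, c.group_b],
                    "mean_diff": c.mean_diff,
                    "p_adj": c.p_adj,
                    "stars": c.stars,
                }
                for c in self.pairwise
            ],
            "summaries": {
                g: {
                    "median": s.median,
                    "q25": s.q25,
                    "q75": s.q75,
                    "outliers": list(s.outliers),
                }
                for g, s in self.summaries.items()
            },
        }


def boxplot_summary(values) -> BoxplotSummary:
    """Median, linearly interpolated quartiles, and Tukey-fence outliers."""
    a = np.asarray(values, dtype=np.float64)
    if a.size == 0:
        raise ValueError("boxplot_summary requires at least one value")
    q25, med, q75 = np.quantile(a, [0.25, 0.5, 0.75], method="linear")
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    outliers = sorted(float(x) for x in a[(a < lo) | (a > hi)])
    return BoxplotSummary(float(med), float(q25), float(q75), outliers)


def two_group_ttest(values_a, values_b, paired: bool = False):
    """Two-tailed Student's t test; unpaired uses the equal-variance statistic."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if paired:
        if a.size != b.size:
            raise ValueError(
                f"paired test requires equal lengths, got {a.size} and {b.size}"
            )
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def anova_multicompare(
    metrics: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    posthoc: str = "tukey",
) -> GroupComparison:
    """One-way ANOVA + family-wise-corrected pairwise comparisons for a metric.

    ``posthoc`` is ``"tukey"`` (Tukey HSD, the default) or ``"bonferroni"``
    (pairwise equal-variance t tests with Bonferroni-adjusted p-values).
    """
    if metric not in metrics.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    if group_col not in metrics.columns:
        raise KeyError(f"group column {group_col!r} not in table")
    labels = list(dict.fromkeys(metrics[group_col]))  # stable group order
    if len(labels) < 2:
        raise ValueError("anova_multicompare requires at least two groups")
    samples = {}
    for g in labels:
        vals = np.asarray(
            metrics.loc[metrics[group_col] == g, metric], dtype=np.float64
        )
        if vals.size < 2:
            raise ValueError(
                f"group {g!r} has {vals.size} observation(s); need at least 2"
            )
        samples[g] = vals
    if all(np.ptp(v) == 0 for v in samples.values()):
        raise ValueError(
            f"metric {metric!r}: zero within-group variance in every group; "
            "F statistic undefined"
        )
    f_stat, p_value = sps.f_oneway(*samples.values())

    pairwise: list[PairwiseComparison] = []
    if posthoc == "tukey":
        res = sps.tukey_hsd(*samples.values())
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p = float(res.pvalue[i, j])
                pairwise.append(
                    PairwiseComparison(
                        labels[i],
                        labels[j],
                        float(samples[labels[i]].mean() - samples[labels[j]].mean()),
                        p,
                        significance_stars(p),
                    )
                )
    elif posthoc == "bonferroni":
        n_pairs = len(labels) * (len(labels) - 1) // 2
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                _, p_raw = two_group_ttest(samples[labels[i]], samples[labels[j]])
                p = min(p_raw * n_pairs, 1.0)
                pairwise.append(
                    PairwiseComparison(
                        labels[i],
                        labels[j],
                        float(samples[labels[i]].mean() - samples[labels[j]].mean()),
                        p,
                        significance_stars(p),
                    )
                )
    else:
        raise ValueError(f"unknown posthoc method {posthoc!r}")

    summaries = {g: boxplot_summary(v) for g, v in samples.items()}
    return GroupComparison(
        metric=metric,
        groups=labels,
        n_per_group={g: int(v.size) for g, v in samples.items()},
        f_stat=float(f_stat),
        p_value=float(p_value),
        posthoc_method=posthoc,
        pairwise=pairwise,
        summaries=summaries,
    )
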