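"""Group comparisons over black-pixel cohort outputs.

Two-group comparisons use Student's t test or the Mann-Whitney U test
(``method="auto"`` gates on Shapiro-Wilk normality of both groups at
alpha=0.05); three or more groups use one-way ANOVA with Tukey-Kramer
post-hoc pairwise contrasts (honest significant difference generalized to
unequal group sizes). All tests are two-sided; the working significance
level is 0.05.

Repeated acquisitions contribute one summary value per lesion per timepoint,
so the multi-group comparison is a one-way ANOVA on those summaries rather
than a full repeated-measures model — a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import SampleSizeError

ALPHA = 0.05


@dataclass
class GroupComparison:
    labels: tuple
    n: tuple
    means: tuple
    sds: tuple
    method: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _describe(groups):
    ns = tuple(len(g) for g in groups)
    means = tuple(float(np.mean(g)) for g in groups)
    sds = tuple(float(np.std(g, ddof=1)) for g in groups)
    return ns, means, sds


def compare_two_groups(a, b, method: str = "auto", labels=("a", "b")) -> GroupComparison:
    """Two-sided two-group comparison of per-lesion summary values.

    ``method``: ``"t"`` (Student's t), ``"mannwhitney"``, or ``"auto"``
    (t when Shapiro-Wilk does not reject normality for either group at 0.05,
    Mann-Whitney otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs at least 2 observations")

    chosen = method
    if method == "auto":
        normal = all(
            g.size < 3 or np.ptp(g) == 0 or stats.shapiro(g).pvalue > ALPHA
            for g in (a, b)
        )
        chosen = "t" if normal else "mannwhitney"

    if chosen == "t":
        res = stats.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # zero variance in both groups, identical means
            stat, p = 0.0, 1.0
    elif chosen == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    ns, means, sds = _describe((a, b))
    return GroupComparison(
        labels=tuple(labels),
        n=ns,
        means=means,
        sds=sds,
        method=chosen,
        statistic=stat,
        p_value=min(p, 1.0),
        extra={"requested_method": method},
    )


def anova_tukey(groups, labels=None, pairwise: bool = True) -> GroupComparison:
    """One-way ANOVA with Tukey-Kramer pairwise post-hoc contrasts.

    Requires at least three groups (use :func:`compare_two_groups` for two);
    the pairwise table covers every unordered pair with the Tukey-adjusted
    p value and the reject decision at alpha=0.05. ``pairwise=False`` skips
    the post-hoc table (the omnibus F test is unchanged) — useful in large
    simulation loops where only the omnibus decision is consumed, since the
    studentized-range evaluation dominates the runtime.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise SampleSizeError(
            "anova_tukey needs >= 3 groups; use compare_two_groups for two"
        )
    for g in groups:
        if g.size < 2:
            raise SampleSizeError("each group needs at least 2 observations")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(groups)))
    labels = tuple(str(l) for l in labels)

    f_res = stats.f_oneway(*groups)
    table = None
    if pairwise:
        values = np.concatenate(groups)
        codes = np.repeat(labels, [g.size for g in groups])
        tk = pairwise_tukeyhsd(values, codes, alpha=ALPHA)
        uniq = np.unique(codes)  # statsmodels orders pairs over sorted labels
        pairs = [
            (uniq[i], uniq[j])
            for i in range(len(uniq))
            for j in range(i + 1, len(uniq))
        ]
        table = pd.DataFrame(
            {
                "group1": [p[0] for p in pairs],
                "group2": [p[1] for p in pairs],
                "meandiff": tk.meandiffs,
                "p-adj": tk.pvalues,
                "lower": tk.confint[:, 0],
                "upper": tk.confint[:, 1],
                "reject": tk.reject,
            }
        )

    ns, means, sds = _describe(groups)
    return GroupComparison(
        labels=labels,
        n=ns,
        means=means,
        sds=sds,
        method="anova+tukey-kramer",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        pairwise=table,
    )
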