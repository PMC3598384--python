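"""Approach IV: the person-centred (adaptation-groups) methodology.

Children are cross-classified by tertiles of the cumulative adversity index
and of one informant's Time-2 SDQ difficulties:

* Resilient        = high adversity + low difficulties
* Maladaptive      = high adversity + high difficulties
* Competent        = low adversity + low difficulties
* HighlyVulnerable = low adversity + high difficulties
* Unclassified     = middle tertile on either variable (excluded from the
  group comparisons by default)

The four extreme groups are compared on the resource variables with a
gender-adjusted MANCOVA, Bonferroni-adjusted univariate tests, and three
planned contrasts per resource (Resilient vs Maladaptive, Resilient vs
Competent, Competent vs HighlyVulnerable) with RMS-pooled Cohen's d.  When
Levene's test rejects variance homogeneity for a resource, the Kruskal-
Wallis and Mann-Whitney tests replace the parametric omnibus and contrasts.

The pattern label per resource follows the canonical person-centred logic:
a resource that separates Resilient from Maladaptive children *and*
Competent from HighlyVulnerable children is promotive; one that separates
only the high-adversity pair is protective; only the low-adversity pair,
reactive.  The Resilient-vs-Competent contrast is reported but not
load-bearing for the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import (ALPHA, ContrastResult, ManovaResult, chi_square_independence,
                    cohens_d, mancova, tertile_split, two_proportion_z)

__all__ = [
    "GROUP_LABELS",
    "AdaptationGroups",
    "GroupDistributionTests",
    "GroupComparison",
    "form_adaptation_groups",
    "group_distribution_tests",
    "compare_groups",
]

GROUP_LABELS = ("Resilient", "Maladaptive", "Competent", "HighlyVulnerable", "Unclassified")

PLANNED_PAIRS = (("Resilient", "Maladaptive"),
                 ("Resilient", "Competent"),
                 ("Competent", "HighlyVulnerable"))


@dataclass
class AdaptationGroups:
    informant: str
    labels: pd.Series
    counts: dict[str, int]
    adversity_tertile: pd.Series
    sdq_tertile: pd.Series

    @property
    def classified_index(self) -> pd.Index:
        return self.labels.index[self.labels != "Unclassified"]


def form_adaptation_groups(
    adversity: pd.Series,
    sdq_t2: pd.Series,
    informant: str,
    include_middle: bool = False,
) -> AdaptationGroups:
    """Cross-classify adversity and SDQ tertiles into adaptation groups.

    With ``include_middle`` the middle tertiles are retained by collapsing
    the classification to a 2x2 on (low+mid vs high adversity) x (low+mid vs
    high SDQ) median-free variant; by default middle-tertile children on
    either variable are Unclassified.
    """
    adv_t = pd.Series(tertile_split(adversity), index=adversity.index)
    sdq_t = pd.Series(tertile_split(sdq_t2), index=sdq_t2.index)

    def classify(a: str, s: str) -> str:
        if include_middle:
            a = "high" if a == "high" else "low"
            s = "high" if s == "high" else "low"
        if a == "high" and s == "low":
            return "Resilient"
        if a == "high" and s == "high":
            return "Maladaptive"
        if a == "low" and s == "low":
            return "Competent"
        if a == "low" and s == "high":
            return "HighlyVulnerable"
        return "Unclassified"

    labels = pd.Series([classify(a, s) for a, s in zip(adv_t, sdq_t)],
                       index=adversity.index, name="adaptation_group")
    counts = {g: int((labels == g).sum()) for g in GROUP_LABELS}
    return AdaptationGroups(informant=informant, labels=labels, counts=counts,
                            adversity_tertile=adv_t, sdq_tertile=sdq_t)


@dataclass
class GroupDistributionTests:
    chi2: float
    chi2_df: int
    chi2_p: float
    z: float
    z_p: float
    pct_low_adversity_good: float        # Competent share of the low-adversity tertile
    pct_high_adversity_good: float       # Resilient share of the high-adversity tertile
    table: pd.DataFrame = field(repr=False, default=None)


def group_distribution_tests(groups: AdaptationGroups) -> GroupDistributionTests:
    """Chi-square on the full 3x3 tertile table and the two-proportion z test
    comparing the low-difficulties share of the low- vs high-adversity groups."""
    table = pd.crosstab(groups.adversity_tertile, groups.sdq_tertile)
    order = ["low", "mid", "high"]
    table = table.reindex(index=order, columns=order, fill_value=0)
    chi2, df, p = chi_square_independence(table.to_numpy())

    n_low = int((groups.adversity_tertile == "low").sum())
    n_high = int((groups.adversity_tertile == "high").sum())
    k_competent = groups.counts["Competent"]
    k_resilient = groups.counts["Resilient"]
    z, z_p = two_proportion_z(k_competent, n_low, k_resilient, n_high)
    return GroupDistributionTests(
        chi2=chi2, chi2_df=df, chi2_p=p, z=z, z_p=z_p,
        pct_low_adversity_good=100.0 * k_competent / n_low,
        pct_high_adversity_good=100.0 * k_resilient / n_high,
        table=table,
    )


@dataclass
class GroupComparison:
    manova: ManovaResult
    resources: tuple[str, ...]
    univariate: pd.DataFrame
    contrasts: dict[str, list[ContrastResult]]
    patterns: dict[str, str]
    nonparametric: dict[str, bool]
    group_stats: pd.DataFrame

    def contrast_summary(self, resource: str) -> str:
        """E.g. '1 > 2; 1 = 3; 3 > 4' in the conventional group numbering."""
        num = {"Resilient": 1, "Maladaptive": 2, "Competent": 3, "HighlyVulnerable": 4}
        parts = []
        for c in self.contrasts[resource]:
            if not c.significant:
                op = "="
            else:
                op = ">" if c.mean_difference > 0 else "<"
            parts.append(f"{num[c.group_a]} {op} {num[c.group_b]}")
        return "; ".join(parts)


def _pattern(contrasts: list[ContrastResult]) -> str:
    by_pair = {(c.group_a, c.group_b): c for c in contrasts}
    rm = by_pair[("Resilient", "Maladaptive")]
    chv = by_pair[("Competent", "HighlyVulnerable")]
    rm_up = rm.significant and rm.mean_difference > 0
    chv_up = chv.significant and chv.mean_difference > 0
    if rm_up and chv_up:
        return "promotive"
    if rm_up and not chv.significant:
        return "protective"
    if chv_up and not rm.significant:
        return "reactive"
    return "null"


def compare_groups(
    cohort: pd.DataFrame,
    groups: AdaptationGroups,
    resources: tuple[str, ...],
    covariate: str = "gender",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Gender-adjusted MANCOVA plus planned contrasts over the four groups.

    Contrast p-values are Bonferroni-adjusted within each resource's family
    of three planned comparisons; effect sizes are RMS-pooled Cohen's d on
    the raw (unadjusted) group means.
    """
    idx = groups.classified_index
    sub = cohort.loc[idx]
    labels = groups.labels.loc[idx]
    for g in GROUP_LABELS[:4]:
        if (labels == g).sum() < 5:
            raise ValueError(f"adaptation group {g!r} has n < 5")

    man = mancova(sub[list(resources)].to_numpy(), labels.to_numpy(),
                  sub[covariate].to_numpy() if covariate else None)
    uni = man.univariate.copy()
    uni["dv"] = list(resources)
    uni = uni.set_index("dv")

    stats_rows = []
    contrasts: dict[str, list[ContrastResult]] = {}
    nonparametric: dict[str, bool] = {}
    patterns: dict[str, str] = {}
    for r in resources:
        samples = {g: sub.loc[labels == g, r].to_numpy() for g in GROUP_LABELS[:4]}
        for g, x in samples.items():
            stats_rows.append({"resource": r, "group": g, "n": len(x),
                               "mean": x.mean(), "sd": x.std(ddof=1)})
        lev_p = sps.levene(*samples.values(), center="median").pvalue
        use_np = bool(lev_p < alpha)
        nonparametric[r] = use_np
        if use_np:
            kw = sps.kruskal(*samples.values())
            uni.loc[r, ["F", "p"]] = [kw.statistic, kw.pvalue]
            uni.loc[r, "p_bonferroni"] = min(1.0, kw.pvalue * len(resources))
            uni.loc[r, "significant"] = kw.pvalue * len(resources) < alpha

        rows = []
        for a, b in PLANNED_PAIRS:
            xa, xb = samples[a], samples[b]
            if use_np:
                stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
                test = "mannwhitney"
            else:
                stat, p = sps.ttest_ind(xa, xb, equal_var=True)
                test = "t"
            p_adj = min(1.0, p * len(PLANNED_PAIRS))
            rows.append(ContrastResult(
                group_a=a, group_b=b,
                mean_a=float(xa.mean()), mean_b=float(xb.mean()),
                sd_a=float(xa.std(ddof=1)), sd_b=float(xb.std(ddof=1)),
                n_a=len(xa), n_b=len(xb),
                mean_difference=float(xa.mean() - xb.mean()),
                d=cohens_d(xa.mean(), xa.std(ddof=1), len(xa),
                           xb.mean(), xb.std(ddof=1), len(xb)),
                statistic=float(stat), pvalue=float(p), p_adjusted=float(p_adj),
                significant=bool(p_adj < alpha), test=test,
            ))
        contrasts[r] = rows
        patterns[r] = _pattern(rows)

    return GroupComparison(
        manova=man,
        resources=tuple(resources),
        univariate=uni,
        contrasts=contrasts,
        patterns=patterns,
        nonparametric=nonparametric,
        group_stats=pd.DataFrame(stats_rows),
    )
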