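"""Approaches II and III: resilience residuals and multiple-groups comparison.

Approach II regresses Time-2 SDQ difficulties on the cumulative adversity
index, reverse-codes the standardized residuals (so positive = fewer
difficulties than adversity predicts = more resilient), and then regresses
those residual scores on gender (Step 1) and the resource factors (Step 2).

Approach III refits the same residual model separately inside the low- and
high-adversity tertiles and compares the standardized betas descriptively:
similar betas in both strata mark a promotive factor, a meaningfully larger
beta under high adversity a protective one, and a benefit concentrated in
the low-adversity stratum a (protective-)reactive one.  The difference
threshold separating "similar" from "differential" defaults to .15 in beta
units and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interaction import DIFFERENTIAL_THRESHOLD, default_resources
from .stats import (ALPHA, StepwiseModelResult, hierarchical_regression,
                    reverse_coded_residuals, tertile_split)

__all__ = [
    "ResilienceResiduals",
    "EffectPattern",
    "compute_resilience_residuals",
    "regress_residuals",
    "multigroup_compare",
]


@dataclass
class ResilienceResiduals:
    """Continuous vulnerability-to-resilience scores for one outcome informant."""

    outcome: str
    scores: pd.Series
    resilient_flag: pd.Series            # score > 0 (ties -> vulnerable)
    percent_resilient: float
    n_zero_ties: int


@dataclass
class EffectPattern:
    """Low- vs high-adversity comparison of one resource's effect."""

    resource: str
    beta_low: float
    beta_high: float
    p_low: float
    p_high: float
    difference: float                    # beta_low - beta_high
    label: str                           # promotive/protective/reactive/protective-reactive/null


def compute_resilience_residuals(
    cohort: pd.DataFrame,
    outcome: str,
    adversity: str = "adversity_index",
) -> ResilienceResiduals:
    """Reverse-coded standardized residuals of an SDQ outcome on adversity."""
    for col in (outcome, adversity):
        if col not in cohort.columns:
            raise ValueError(f"missing column {col!r}")
    scores = pd.Series(
        reverse_coded_residuals(cohort[outcome], cohort[adversity]),
        index=cohort.index,
        name=f"{outcome}_resilience",
    )
    flags = scores > 0
    return ResilienceResiduals(
        outcome=outcome,
        scores=scores,
        resilient_flag=flags,
        percent_resilient=float(flags.mean() * 100.0),
        n_zero_ties=int((scores == 0).sum()),
    )


def regress_residuals(
    residuals: ResilienceResiduals | pd.Series,
    cohort: pd.DataFrame,
    resources: tuple[str, ...],
    covariates: tuple[str, ...] = ("gender",),
) -> StepwiseModelResult:
    """Two-step model: covariates at Step 1, all resources at Step 2."""
    scores = residuals.scores if isinstance(residuals, ResilienceResiduals) else residuals
    df = cohort.loc[scores.index, list(covariates) + list(resources)].copy()
    df["_resilience"] = scores
    blocks = [b for b in (list(covariates), list(resources)) if b]
    return hierarchical_regression(df, "_resilience", blocks)


def _label(beta_low: float, beta_high: float, sig_low: bool, sig_high: bool,
           threshold: float) -> str:
    diff = beta_high - beta_low
    if abs(diff) < threshold:
        if not (sig_low or sig_high):
            return "null"
        if beta_low * beta_high < 0 and (sig_low and sig_high):
            return "null"  # opposing significant effects do not form a pattern
        return "promotive"
    if diff >= threshold:
        return "protective"
    # benefit concentrated under low adversity
    if sig_high and beta_high > 0:
        return "protective-reactive"
    return "reactive"


def multigroup_compare(
    cohort: pd.DataFrame,
    outcome: str,
    resources: tuple[str, ...] | None = None,
    covariates: tuple[str, ...] = ("gender",),
    adversity: str = "adversity_index",
    threshold: float = DIFFERENTIAL_THRESHOLD,
    refit_residuals: bool = False,
    min_group_n: int = 30,
) -> tuple[list[EffectPattern], dict[str, StepwiseModelResult]]:
    """Fit the residual model inside the low- and high-adversity tertiles.

    By default the residual-generating regression is fitted on the whole
    sample (the subgroup models then predict whole-sample residual scores);
    with ``refit_residuals`` the residuals are regenerated within each
    tertile.  Returns the per-resource effect patterns and the fitted
    whole-sample / low / high models.
    """
    if resources is None:
        informant = "parent" if outcome.startswith("p_") else "teacher"
        resources = default_resources(informant)
    tert = pd.Series(tertile_split(cohort[adversity]), index=cohort.index)

    whole = compute_resilience_residuals(cohort, outcome, adversity)
    models: dict[str, StepwiseModelResult] = {
        "whole": regress_residuals(whole, cohort, resources, covariates)
    }
    for stratum in ("low", "high"):
        sub = cohort[tert == stratum]
        if len(sub) < min_group_n:
            raise ValueError(f"{stratum}-adversity subgroup too small (n={len(sub)})")
        if refit_residuals:
            res = compute_resilience_residuals(sub, outcome, adversity)
        else:
            res = ResilienceResiduals(
                outcome=outcome,
                scores=whole.scores[sub.index],
                resilient_flag=whole.resilient_flag[sub.index],
                percent_resilient=float((whole.scores[sub.index] > 0).mean() * 100),
                n_zero_ties=0,
            )
        models[stratum] = regress_residuals(res, sub, resources, covariates)

    patterns = []
    for r in resources:
        b_lo = models["low"].final.betas[r]
        b_hi = models["high"].final.betas[r]
        p_lo = models["low"].final.pvalues[r]
        p_hi = models["high"].final.pvalues[r]
        patterns.append(EffectPattern(
            resource=r,
            beta_low=b_lo,
            beta_high=b_hi,
            p_low=p_lo,
            p_high=p_hi,
            difference=b_lo - b_hi,
            label=_label(b_lo, b_hi, p_lo < ALPHA, p_hi < ALPHA, threshold),
        ))
    return patterns, models
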