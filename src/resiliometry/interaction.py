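"""Approach I: the statistical-interaction (moderated regression) methodology.

A four-step hierarchical regression predicting Time-2 SDQ difficulties:
gender at Step 1, the cumulative adversity index at Step 2, the four resource
main effects at Step 3, and the adversity x resource product terms at Step 4.
All continuous variables are centred (z-scored) before product terms are
formed; product columns are left on the product-of-z scale so that the
fitted interaction coefficient is directly comparable to a structural
interaction beta.

A significant interaction is probed with simple slopes at the moderator's
mean +/- 1 SD and classified as protective, protective-reactive or reactive
from the direction of the implied benefit change across adversity.  Beyond
significance, classification requires the benefit difference across +/-1 SD
of adversity (|2 b_int|) to exceed the same differential-effect threshold
used by the multiple-groups approach, so that trivially small but
significant moderation in large samples is not over-labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ALPHA, StepwiseModelResult, hierarchical_regression, zscore

__all__ = [
    "InteractionModelSpec",
    "InteractionResult",
    "SimpleSlopes",
    "default_resources",
    "fit_interaction_model",
    "simple_slopes",
]

DIFFERENTIAL_THRESHOLD = 0.15  # standardized benefit difference across +/-1 SD adversity


def default_resources(informant: str, pooled: bool = False) -> tuple[str, ...]:
    """Informant-matched resource set for a given outcome informant.

    Self-concept and self-control follow the outcome's informant; the
    relationship scales have fixed informants (parents rate the child-parent
    relationship, teachers the child-teacher relationship).  With ``pooled``
    both informants' self-concept and self-control enter.
    """
    if informant not in ("parent", "teacher"):
        raise ValueError("informant must be 'parent' or 'teacher'")
    pre = "p" if informant == "parent" else "t"
    if pooled:
        selfs = ("p_self_concept", "t_self_concept", "p_self_control", "t_self_control")
    else:
        selfs = (f"{pre}_self_concept", f"{pre}_self_control")
    return selfs + ("p_child_parent_rel", "t_child_teacher_rel")


@dataclass
class InteractionModelSpec:
    outcome: str                                   # 'p_sdq_t2' or 't_sdq_t2'
    covariates: tuple[str, ...] = ("gender",)
    adversity: str = "adversity_index"
    resources: tuple[str, ...] | None = None
    center: bool = True
    threshold: float = DIFFERENTIAL_THRESHOLD

    def __post_init__(self):
        if self.resources is None:
            informant = "parent" if self.outcome.startswith("p_") else "teacher"
            self.resources = default_resources(informant)


@dataclass
class SimpleSlopes:
    """Adversity-on-outcome slopes at moderator mean +/- 1 SD, with the
    complementary resource-benefit reading used for classification."""

    moderator: str
    slope_low: float
    slope_high: float
    benefit_low_adversity: float
    benefit_high_adversity: float
    interaction_beta: float
    interaction_p: float
    classification: str
    plot_data: pd.DataFrame = field(repr=False, default=None)


@dataclass
class InteractionResult:
    spec: InteractionModelSpec
    model: StepwiseModelResult
    interaction_terms: dict[str, str]              # resource -> product column name
    slopes: dict[str, SimpleSlopes]

    def classification(self, resource: str) -> str:
        return self.slopes[resource].classification


def _product_name(adversity: str, resource: str) -> str:
    return f"{adversity}_x_{resource}"


def fit_interaction_model(cohort: pd.DataFrame, spec: InteractionModelSpec) -> InteractionResult:
    """Fit the four-step moderation model and classify each interaction."""
    cols = list(spec.covariates) + [spec.adversity] + list(spec.resources) + [spec.outcome]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    df = cohort[cols].astype(float).copy()
    if df.isna().any().any():
        raise ValueError("complete cases required")

    # Centre via z-scoring (centering leaves the interaction coefficient and
    # its p-value unchanged; z-scoring additionally puts betas on a common
    # scale).  Products of z-scores are used as-is.
    work = df.apply(zscore, raw=False) if spec.center else df
    products = {}
    for r in spec.resources:
        pname = _product_name(spec.adversity, r)
        work[pname] = work[spec.adversity] * work[r]
        products[r] = pname

    blocks = [list(spec.covariates), [spec.adversity], list(spec.resources),
              list(products.values())]
    model = hierarchical_regression(work, spec.outcome, blocks, standardize=False)

    result = InteractionResult(spec=spec, model=model, interaction_terms=products, slopes={})
    for r in spec.resources:
        result.slopes[r] = simple_slopes(result, r)
    return result


def simple_slopes(result: InteractionResult, moderator: str,
                  sd_moderator: float = 1.0, sd_adversity: float = 1.0) -> SimpleSlopes:
    """Probe an adversity x resource interaction at moderator mean +/- 1 SD.

    slope_low/high are the adversity slopes at low/high moderator; the
    benefit entries are the resource's beneficial effect (sign-flipped
    resource slope, since the outcome is a difficulties score) at adversity
    mean -/+ 1 SD.  Classification:

    * ``none`` -- interaction non-significant, or benefit difference below
      the differential-effect threshold;
    * ``protective`` -- benefit larger under high adversity;
    * ``protective-reactive`` -- benefit smaller under high adversity but
      still positive;
    * ``reactive`` -- benefit present under low adversity only.
    """
    spec = result.spec
    pname = result.interaction_terms.get(moderator)
    if pname is None:
        raise ValueError(f"model has no adversity x {moderator} term")
    final = result.model.final
    b_adv = final.betas[spec.adversity]
    b_res = final.betas[moderator]
    b_int = final.betas[pname]
    p_int = final.pvalues[pname]

    slope_low = b_adv - sd_moderator * b_int
    slope_high = b_adv + sd_moderator * b_int
    benefit_low = -(b_res - sd_adversity * b_int)
    benefit_high = -(b_res + sd_adversity * b_int)

    if p_int >= ALPHA or abs(benefit_high - benefit_low) < spec.threshold:
        label = "none"
    elif benefit_high > benefit_low:
        label = "protective"
    elif benefit_high > 0:
        label = "protective-reactive"
    else:
        label = "reactive"

    # Aiken & West-style plot coordinates: predicted outcome at the four
    # combinations of adversity and moderator at mean +/- 1 SD.
    rows = []
    for mod in (-1.0, 1.0):
        for adv in (-1.0, 1.0):
            rows.append({
                "moderator_sd": mod, "adversity_sd": adv,
                "predicted": b_adv * adv + b_res * mod + b_int * adv * mod,
            })
    return SimpleSlopes(
        moderator=moderator,
        slope_low=slope_low,
        slope_high=slope_high,
        benefit_low_adversity=benefit_low,
        benefit_high_adversity=benefit_high,
        interaction_beta=b_int,
        interaction_p=p_int,
        classification=label,
        plot_data=pd.DataFrame(rows),
    )
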