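"""Cumulative family adversity: the 11 indicators and the composite index.

Eleven Time-1 family adversity indicators fall into five groups:

* socio-economic status (SES): mother's education, father's education,
  family full-time-equivalent employment, welfare-benefit receipt, and
  living with three or more siblings;
* parental separation: single-parent family, years lived apart from the two
  natural parents (0-6);
* early parenthood: mother and father aged 20 or younger at the child's
  birth;
* parental psychological distress: GHQ-12 total (binary-scored);
* stressful life events: LTE-Q tally.

Every indicator is oriented so that higher = more adversity.  The composite
index z-scores each indicator, averages the z-scores within multi-indicator
groups, z-scores the five resulting group scores, and sums them -- so the
five groups contribute equal weight, the total has sample mean 0 by
construction, and its SD depends on the inter-group correlations (reported,
never forced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "INDICATORS",
    "ADVERSITY_GROUPS",
    "CompositeAdversityIndex",
    "derive_indicators",
    "build_composite_index",
    "collinearity_screen",
]

ADVERSITY_GROUPS: dict[str, tuple[str, ...]] = {
    "ses": ("mother_education", "father_education", "family_employment",
            "benefit_receipt", "three_plus_siblings"),
    "separation": ("single_parent", "years_separated"),
    "early_parenthood": ("mother_adolescent", "father_adolescent"),
    "distress": ("ghq_total",),
    "life_events": ("lte_count",),
}

INDICATORS: tuple[str, ...] = tuple(i for g in ADVERSITY_GROUPS.values() for i in g)

ADOLESCENT_PARENT_MAX_AGE = 20  # parent <= 20 years at the child's birth
PLAUSIBLE_PARENT_AGE = (10, 70)


def derive_indicators(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Derive the 11 adversity indicators from raw family fields.

    Expects columns: mother_education, father_education (ordinals, higher =
    lower attainment), family_employment (ordinal, higher = less employment),
    benefit_receipt (0/1), n_siblings (count), single_parent (0/1),
    years_separated (0-6), ghq_total (0-12), lte_count (0-12), and either
    mother_age_at_birth / father_age_at_birth or mother_age / father_age
    together with child_age.

    Returns (indicators, excluded_index): rows with any missing required
    field are dropped (complete-case policy) and their index returned.
    Implausible parental ages raise a validation error.
    """
    df = raw.copy()
    for parent in ("mother", "father"):
        col = f"{parent}_age_at_birth"
        if col not in df.columns:
            if f"{parent}_age" not in df.columns or "child_age" not in df.columns:
                raise ValueError(f"need {col} or {parent}_age plus child_age")
            df[col] = df[f"{parent}_age"] - df["child_age"]

    required = ["mother_education", "father_education", "family_employment",
                "benefit_receipt", "n_siblings", "single_parent", "years_separated",
                "mother_age_at_birth", "father_age_at_birth", "ghq_total", "lte_count"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing raw adversity fields: {missing_cols}")

    complete = df[required].notna().all(axis=1)
    excluded = df.index[~complete]
    df = df.loc[complete]

    lo, hi = PLAUSIBLE_PARENT_AGE
    for col in ("mother_age_at_birth", "father_age_at_birth"):
        bad = df[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            raise ValueError(
                f"implausible {col} (outside {lo}-{hi}) for rows {bad.index[:5].tolist()}"
            )

    out = pd.DataFrame(index=df.index)
    out["mother_education"] = df["mother_education"].astype(float)
    out["father_education"] = df["father_education"].astype(float)
    out["family_employment"] = df["family_employment"].astype(float)
    out["benefit_receipt"] = df["benefit_receipt"].astype(float)
    out["three_plus_siblings"] = (df["n_siblings"] >= 3).astype(float)
    out["single_parent"] = df["single_parent"].astype(float)
    out["years_separated"] = df["years_separated"].astype(float)
    out["mother_adolescent"] = (df["mother_age_at_birth"] <= ADOLESCENT_PARENT_MAX_AGE).astype(float)
    out["father_adolescent"] = (df["father_age_at_birth"] <= ADOLESCENT_PARENT_MAX_AGE).astype(float)
    out["ghq_total"] = df["ghq_total"].astype(float)
    out["lte_count"] = df["lte_count"].astype(float)
    return out, excluded


@dataclass
class CompositeAdversityIndex:
    """Per-child group scores (5 standardized values) and their sum."""

    group_scores: pd.DataFrame
    total: pd.Series
    constants: dict = field(repr=False, default_factory=dict)

    @property
    def sd(self) -> float:
        return float(self.total.std(ddof=1))


def _standardize(s: pd.Series, mean: float, sd: float) -> pd.Series:
    if sd == 0:
        raise ValueError(f"zero-variance indicator: {s.name}")
    return (s - mean) / sd


def build_composite_index(
    indicators: pd.DataFrame,
    order: str = "standardize_then_average",
    weights: dict[str, float] | None = None,
    constants: dict | None = None,
) -> CompositeAdversityIndex:
    """Combine the 11 indicators into the equally weighted 5-group composite.

    ``order`` selects whether multi-indicator groups are averaged over
    indicator z-scores (default) or z-scored after raw averaging; both run the
    same final step (z-score the 5 group scores, then sum).  ``weights`` is an
    experimental per-group weighting (default: all 1).  ``constants`` reuses
    standardization constants from a previous fit (e.g. so a sensitivity rerun
    keeps the full-sample Time-1 scaling); when absent, constants are computed
    on the given sample and stored on the result.
    """
    if order not in ("standardize_then_average", "average_then_standardize"):
        raise ValueError(f"unknown order {order!r}")
    missing = [c for c in INDICATORS if c not in indicators.columns]
    if missing:
        raise ValueError(f"missing indicators: {missing}")
    if len(indicators) < 30:
        raise ValueError("need at least 30 children")
    if constants is None:
        fit = True
        constants = {"order": order, "indicator": {}, "group": {}}
    else:
        fit = False
        if constants.get("order") != order:
            raise ValueError("constants were fitted under a different order")

    groups = {}
    for gname, members in ADVERSITY_GROUPS.items():
        if order == "standardize_then_average" or len(members) == 1:
            zs = []
            for m in members:
                if fit:
                    constants["indicator"][m] = (float(indicators[m].mean()),
                                                 float(indicators[m].std(ddof=1)))
                mu, sd = constants["indicator"][m]
                zs.append(_standardize(indicators[m], mu, sd))
            raw_group = sum(zs) / len(zs)
        else:
            raw_group = indicators[list(members)].mean(axis=1)
        if fit:
            constants["group"][gname] = (float(raw_group.mean()), float(raw_group.std(ddof=1)))
        mu, sd = constants["group"][gname]
        groups[gname] = _standardize(raw_group.rename(gname), mu, sd)

    group_scores = pd.DataFrame(groups)
    w = pd.Series({g: 1.0 for g in ADVERSITY_GROUPS})
    if weights:
        unknown = set(weights) - set(ADVERSITY_GROUPS)
        if unknown:
            raise ValueError(f"unknown group weights: {sorted(unknown)}")
        w.update(pd.Series(weights, dtype=float))
    total = (group_scores * w).sum(axis=1).rename("adversity_index")
    return CompositeAdversityIndex(group_scores=group_scores, total=total, constants=constants)


def collinearity_screen(indicators: pd.DataFrame, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance-inflation factors from regressing each indicator on the rest.

    VIF = 1/(1-R²); values above ``flag_threshold`` are flagged.  Perfectly
    collinear indicators come back as infinite and flagged.
    """
    cols = [c for c in INDICATORS if c in indicators.columns]
    X = indicators[cols].astype(float)
    if X.isna().any().any():
        raise ValueError("complete cases required")
    exog = sm.add_constant(X.to_numpy())
    rows = []
    for j, c in enumerate(cols):
        with np.errstate(divide="ignore"):
            try:
                vif = float(variance_inflation_factor(exog, j + 1))
            except Exception as err:  # singular design
                raise ValueError(f"singular design while screening {c!r}: {err}") from err
        rows.append({"indicator": c, "vif": vif, "flagged": bool(vif > flag_threshold)})
    return pd.DataFrame(rows).set_index("indicator")
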