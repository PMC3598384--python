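"""Full study orchestration: scoring -> adversity index -> Approaches I-IV,
for parent- and teacher-reported outcomes, plus the baseline-exclusion
sensitivity rerun and the cross-method concordance report.

Parent- and teacher-outcome analyses are never pooled into one model; every
run emits one result set per informant.  The adversity index used in a
sensitivity rerun is a Time-1 quantity: when rebuilt from raw fields it
reuses the full-sample standardization constants rather than restandardizing
on the reduced sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import adversity as adv_mod
from . import scoring
from .groups import (AdaptationGroups, GroupComparison, compare_groups,
                     form_adaptation_groups, group_distribution_tests)
from .interaction import (DIFFERENTIAL_THRESHOLD, InteractionModelSpec,
                          InteractionResult, default_resources,
                          fit_interaction_model)
from .residuals import (EffectPattern, ResilienceResiduals,
                        compute_resilience_residuals, multigroup_compare,
                        regress_residuals)
from .stats import ALPHA, StepwiseModelResult

__all__ = [
    "AnalysisConfig",
    "InformantResult",
    "FullAnalysisResult",
    "SensitivityResult",
    "run_full_analysis",
    "sensitivity_rerun",
    "validate_cohort",
]

REQUIRED_ANALYSIS_COLUMNS = (
    "gender", "adversity_index",
    "p_self_concept", "t_self_concept", "p_self_control", "t_self_control",
    "p_child_parent_rel", "t_child_teacher_rel",
    "p_sdq_t2", "t_sdq_t2",
)

APPROACH_NAMES = {1: "interaction", 2: "residuals", 3: "multigroup", 4: "person_centred"}


@dataclass
class AnalysisConfig:
    informants: tuple[str, ...] = ("parent", "teacher")
    approaches: tuple[int, ...] = (1, 2, 3, 4)
    delta_beta_threshold: float = DIFFERENTIAL_THRESHOLD
    alpha: float = ALPHA
    sdq_cutoffs: dict = field(default_factory=lambda: dict(scoring.SDQ_CUTOFFS))
    pooled_resources: bool = False
    include_middle: bool = False
    adversity_source: str = "auto"       # 'auto' | 'column' | 'rebuild'
    refit_subgroup_residuals: bool = False
    seed: int = 0

    def __post_init__(self):
        bad = [i for i in self.informants if i not in ("parent", "teacher")]
        if bad:
            raise ValueError(f"unknown informants: {bad}")
        bad = [a for a in self.approaches if a not in APPROACH_NAMES]
        if bad:
            raise ValueError(f"unknown approaches: {bad}")
        if not self.approaches:
            raise ValueError("at least one approach must be enabled")
        if self.adversity_source not in ("auto", "column", "rebuild"):
            raise ValueError(f"bad adversity_source {self.adversity_source!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("informants", "approaches"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_cohort(cohort: pd.DataFrame, config: AnalysisConfig) -> list[str]:
    """Itemized schema check; returns a list of problems (empty = valid)."""
    problems = []
    for col in REQUIRED_ANALYSIS_COLUMNS:
        if col not in cohort.columns:
            problems.append(f"missing required column {col!r}")
    if "gender" in cohort.columns and not set(cohort["gender"].dropna().unique()) <= {0, 1}:
        problems.append("gender must be coded 0/1 (female = 1)")
    if len(cohort) < 90:
        problems.append(f"cohort too small for tertile-based analyses (n={len(cohort)})")
    return problems


def _prepare(cohort: pd.DataFrame, config: AnalysisConfig,
             adversity_constants: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Scoring and adversity-index stage; returns (analysis table, log)."""
    df = cohort.copy()
    log: dict = {}

    # Composite self-concept from its components when absent.
    for pre in ("p", "t"):
        if (f"{pre}_self_concept" not in df.columns
                and {f"{pre}_self_esteem", f"{pre}_self_efficacy"} <= set(df.columns)):
            df[f"{pre}_self_concept"] = scoring.composite_self_concept(
                df[f"{pre}_self_esteem"], df[f"{pre}_self_efficacy"])

    have_raw = all(c in df.columns for c in
                   ("mother_education", "father_education", "family_employment",
                    "benefit_receipt", "ghq_total", "lte_count"))
    rebuild = (config.adversity_source == "rebuild"
               or (config.adversity_source == "auto" and "adversity_index" not in df.columns))
    if rebuild and not have_raw:
        if config.adversity_source == "rebuild":
            raise ValueError("adversity_source='rebuild' requires the raw family fields")
        rebuild = False              # auto: let schema validation itemize the gap
    if rebuild:
        indicators, excluded = adv_mod.derive_indicators(df)
        composite = adv_mod.build_composite_index(indicators, constants=adversity_constants)
        df = df.loc[indicators.index]
        df["adversity_index"] = composite.total
        log["adversity_rebuilt"] = True
        log["adversity_excluded_rows"] = len(excluded)
        log["adversity_constants"] = composite.constants
    else:
        log["adversity_rebuilt"] = False

    problems = validate_cohort(df, config)
    if problems:
        raise ValueError("cohort failed validation:\n  " + "\n  ".join(problems))

    analysis_cols = [c for c in REQUIRED_ANALYSIS_COLUMNS if c in df.columns]
    complete = df[list(analysis_cols)].notna().all(axis=1)
    log["complete_case_excluded"] = int((~complete).sum())
    return df.loc[complete], log


@dataclass
class InformantResult:
    informant: str
    outcome: str
    resources: tuple[str, ...]
    interaction: InteractionResult | None = None
    residuals: ResilienceResiduals | None = None
    residual_model: StepwiseModelResult | None = None
    multigroup: list[EffectPattern] | None = None
    multigroup_models: dict | None = None
    adaptation_groups: AdaptationGroups | None = None
    distribution_tests: object | None = None
    group_comparison: GroupComparison | None = None


@dataclass
class FullAnalysisResult:
    config: AnalysisConfig
    n: int
    informant_results: dict[str, InformantResult]
    concordance: pd.DataFrame
    manifest: dict

    def to_json(self, path=None) -> str:
        payload = {
            "manifest": self.manifest,
            "concordance": self.concordance.to_dict(orient="records"),
        }
        for informant, res in self.informant_results.items():
            block: dict = {"outcome": res.outcome}
            if res.interaction is not None:
                block["interaction_steps"] = res.interaction.model.to_frame().to_dict("records")
                block["interaction_classification"] = {
                    r: s.classification for r, s in res.interaction.slopes.items()}
            if res.residuals is not None:
                block["percent_resilient"] = res.residuals.percent_resilient
                block["residual_model"] = res.residual_model.to_frame().to_dict("records")
            if res.multigroup is not None:
                block["multigroup"] = [asdict(p) for p in res.multigroup]
            if res.group_comparison is not None:
                gc = res.group_comparison
                block["group_counts"] = res.adaptation_groups.counts
                block["wilks_lambda"] = gc.manova.wilks_lambda
                block["manova_F"] = gc.manova.f_value
                block["manova_df"] = [gc.manova.df1, gc.manova.df2]
                block["manova_partial_eta_sq"] = gc.manova.partial_eta_squared
                block["patterns"] = gc.patterns
                block["contrasts"] = {
                    r: [asdict(c) for c in cs] for r, cs in gc.contrasts.items()}
            payload[informant] = block
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)


def _concordance_label(approach: int, informant_result: InformantResult,
                       resource: str, alpha: float) -> tuple[str, float]:
    """(label, magnitude) of one resource under one approach.

    Magnitudes are each method's primary effect number: the Step-3 benefit
    beta (sign-flipped) for the interaction approach, the residual-model
    beta for the residuals approach, the mean subgroup beta for the
    multiple-groups approach, and the Resilient-vs-Maladaptive d for the
    person-centred approach.
    """
    res = informant_result
    if approach == 1:
        step3 = res.interaction.model.steps[2]
        benefit = -step3.betas[resource]
        cls = res.interaction.slopes[resource].classification
        if cls != "none":
            return cls, benefit
        if step3.pvalues[resource] < alpha and benefit > 0:
            return "promotive", benefit
        return "null", benefit
    if approach == 2:
        final = res.residual_model.final
        beta = final.betas[resource]
        if final.pvalues[resource] < alpha and beta > 0:
            return "promotive", beta
        return "null", beta
    if approach == 3:
        pat = next(p for p in res.multigroup if p.resource == resource)
        return pat.label, (pat.beta_low + pat.beta_high) / 2.0
    if approach == 4:
        gc = res.group_comparison
        rm = gc.contrasts[resource][0]
        return gc.patterns[resource], rm.d
    raise ValueError(approach)


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None,
                      _adversity_constants: dict | None = None) -> FullAnalysisResult:
    """Run every enabled approach for every informant and tabulate concordance."""
    config = config or AnalysisConfig()
    df, log = _prepare(cohort, config, _adversity_constants)

    results: dict[str, InformantResult] = {}
    for informant in config.informants:
        pre = "p" if informant == "parent" else "t"
        outcome = f"{pre}_sdq_t2"
        resources = default_resources(informant, pooled=config.pooled_resources)
        res = InformantResult(informant=informant, outcome=outcome, resources=resources)

        if 1 in config.approaches:
            spec = InteractionModelSpec(outcome=outcome, resources=resources,
                                        threshold=config.delta_beta_threshold)
            res.interaction = fit_interaction_model(df, spec)
        if 2 in config.approaches or 3 in config.approaches:
            res.residuals = compute_resilience_residuals(df, outcome)
            res.residual_model = regress_residuals(res.residuals, df, resources)
        if 3 in config.approaches:
            res.multigroup, res.multigroup_models = multigroup_compare(
                df, outcome, resources,
                threshold=config.delta_beta_threshold,
                refit_residuals=config.refit_subgroup_residuals)
        if 4 in config.approaches:
            res.adaptation_groups = form_adaptation_groups(
                df["adversity_index"], df[outcome], informant,
                include_middle=config.include_middle)
            res.distribution_tests = group_distribution_tests(res.adaptation_groups)
            res.group_comparison = compare_groups(df, res.adaptation_groups,
                                                  resources, alpha=config.alpha)
        results[informant] = res

    rows = []
    for informant, res in results.items():
        for resource in res.resources:
            for a in config.approaches:
                label, mag = _concordance_label(a, res, resource, config.alpha)
                rows.append({"informant": informant, "resource": resource,
                             "approach": APPROACH_NAMES[a], "label": label,
                             "magnitude": mag})
    concordance = pd.DataFrame(rows)

    manifest = {
        "n": len(df),
        "seed": config.seed,
        "config": {**asdict(config)},
        "preparation": {k: v for k, v in log.items() if k != "adversity_constants"},
    }
    return FullAnalysisResult(config=config, n=len(df), informant_results=results,
                              concordance=concordance, manifest=manifest)


@dataclass
class SensitivityResult:
    n_excluded: int
    full: FullAnalysisResult
    reduced: FullAnalysisResult
    attenuation: pd.DataFrame


def sensitivity_rerun(cohort: pd.DataFrame, config: AnalysisConfig | None = None,
                      full: FullAnalysisResult | None = None) -> SensitivityResult:
    """Rerun all approaches excluding children clinical on baseline SDQ.

    Children above the clinical cut-off on *either* parent- (>14) or
    teacher-reported (>12) Time-1 SDQ are removed; the attenuation table
    compares the resource block's incremental variance (residual-model Step-2
    ΔR²) between the full and reduced runs.
    """
    config = config or AnalysisConfig()
    for col in ("p_sdq_t1", "t_sdq_t1"):
        if col not in cohort.columns:
            raise ValueError(f"baseline column {col!r} required for the sensitivity rerun")
    cut_p = config.sdq_cutoffs["parent"]
    cut_t = config.sdq_cutoffs["teacher"]
    clinical = (cohort["p_sdq_t1"] > cut_p) | (cohort["t_sdq_t1"] > cut_t)
    reduced_df = cohort.loc[~clinical]
    if reduced_df.empty:
        raise ValueError("every child is above a baseline clinical cut-off; nothing to analyse")

    if full is None:
        full = run_full_analysis(cohort, config)
    # When the index is rebuilt from raw fields, the rerun reuses the
    # full-sample standardization constants (the index is a Time-1 quantity).
    constants = None
    if full.manifest["preparation"].get("adversity_rebuilt"):
        indicators, _ = adv_mod.derive_indicators(cohort)
        constants = adv_mod.build_composite_index(indicators).constants
    reduced = run_full_analysis(reduced_df, config, _adversity_constants=constants)

    rows = []
    for informant in config.informants:
        rf = full.informant_results[informant]
        rr = reduced.informant_results[informant]
        if rf.residual_model is not None and rr.residual_model is not None:
            rows.append({
                "informant": informant,
                "delta_r2_full": rf.residual_model.final.delta_r_squared,
                "delta_r2_reduced": rr.residual_model.final.delta_r_squared,
                "attenuation": rf.residual_model.final.delta_r_squared
                               - rr.residual_model.final.delta_r_squared,
            })
    return SensitivityResult(
        n_excluded=int(clinical.sum()),
        full=full,
        reduced=reduced,
        attenuation=pd.DataFrame(rows),
    )
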