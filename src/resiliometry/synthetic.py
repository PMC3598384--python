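"""Synthetic multi-informant cohort generator.

Generates cohorts with the statistical structure the resilience analyses
assume: a latent multivariate normal over the continuous analysis variables
calibrated to a published-style correlation surface (means, SDs and
pairwise correlations of parent- and teacher-reported self-esteem,
self-efficacy, self-control, relationship quality, the cumulative adversity
index and Time-2 SDQ difficulties), a binary gender with a configurable
point-biserial effect on teacher-reported SDQ, Gaussian-copula raw adversity
fields thresholded to target prevalences, baseline (Time-1) SDQ scores
calibrated to the reported clinical rates, optional item-level responses
with approximate target alphas, and configurable injected promotive /
protective resource effects for scenario studies.

Randomness is split into named streams per variable family (analysis
latents, gender, raw adversity fields, baseline, items) so that enabling one
family does not perturb the draws of another under the same seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import scoring

__all__ = [
    "ANALYSIS_VARIABLES",
    "DEFAULT_CORRELATIONS",
    "InjectedEffect",
    "GeneratorConfig",
    "SyntheticCohort",
    "CalibrationReport",
    "generate_cohort",
    "check_calibration",
    "default_config",
    "null_effect_config",
    "E_TOP_THIRD",
]

# Mean of a standard normal conditional on falling in its top third;
# by symmetry the bottom-third mean is its negative.  Used when designing
# injected scenarios whose effects are pinned at tertile centres.
E_TOP_THIRD = float(sps.norm.pdf(sps.norm.ppf(2 / 3)) * 3)


@dataclass(frozen=True)
class AnalysisVariable:
    name: str
    mean: float
    sd: float
    lo: float
    hi: float
    integer: bool


def _t1_sd(mean: float, cutoff: int, clinical_rate: float) -> float:
    # Solve the normal SD so that P(rounded total > cutoff) equals the rate.
    return (cutoff + 0.5 - mean) / sps.norm.ppf(1 - clinical_rate)


# Calibration surface: marginal means/SDs of the continuous analysis
# variables, plus baseline SDQ scores whose SDs are solved from the reported
# Time-1 clinical proportions (5.3% parent, 5.9% teacher).
ANALYSIS_VARIABLES: tuple[AnalysisVariable, ...] = (
    AnalysisVariable("p_self_esteem", 55.47, 6.10, 14, 70, True),
    AnalysisVariable("t_self_esteem", 57.28, 8.48, 14, 70, True),
    AnalysisVariable("p_self_efficacy", 28.92, 3.90, 9, 36, True),
    AnalysisVariable("t_self_efficacy", 30.01, 5.29, 9, 36, True),
    AnalysisVariable("p_self_control", 20.67, 4.05, 8, 40, True),
    AnalysisVariable("t_self_control", 23.75, 5.57, 8, 40, True),
    AnalysisVariable("p_child_parent_rel", 65.54, 6.38, 15, 75, True),
    AnalysisVariable("t_child_teacher_rel", 68.19, 7.71, 15, 75, True),
    AnalysisVariable("adversity_index", 0.00, 3.06, -np.inf, np.inf, False),
    AnalysisVariable("p_sdq_t2", 8.24, 5.43, 0, 40, True),
    AnalysisVariable("t_sdq_t2", 6.94, 6.21, 0, 40, True),
    AnalysisVariable("p_sdq_t1", 8.47, _t1_sd(8.47, 14, 0.053), 0, 40, True),
    AnalysisVariable("t_sdq_t1", 5.28, _t1_sd(5.28, 12, 0.059), 0, 40, True),
)

PRIMARY_NAMES = tuple(v.name for v in ANALYSIS_VARIABLES[:11])
BASELINE_NAMES = ("p_sdq_t1", "t_sdq_t1")
RESOURCE_NAMES = PRIMARY_NAMES[:8]
OUTCOME_NAMES = ("p_sdq_t2", "t_sdq_t2")

# Pairwise correlations among the primary analysis variables (self-concept
# composites are derived downstream, not generated).
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("p_self_esteem", "t_self_esteem"): 0.18,
    ("p_self_esteem", "p_self_efficacy"): 0.64,
    ("t_self_esteem", "p_self_efficacy"): 0.17,
    ("p_self_esteem", "t_self_efficacy"): 0.16,
    ("t_self_esteem", "t_self_efficacy"): 0.86,
    ("p_self_efficacy", "t_self_efficacy"): 0.21,
    ("p_self_esteem", "p_self_control"): 0.45,
    ("t_self_esteem", "p_self_control"): 0.13,
    ("p_self_efficacy", "p_self_control"): 0.47,
    ("t_self_efficacy", "p_self_control"): 0.15,
    ("p_self_esteem", "t_self_control"): 0.09,
    ("t_self_esteem", "t_self_control"): 0.64,
    ("p_self_efficacy", "t_self_control"): 0.14,
    ("t_self_efficacy", "t_self_control"): 0.61,
    ("p_self_control", "t_self_control"): 0.14,
    ("p_self_esteem", "p_child_parent_rel"): 0.52,
    ("t_self_esteem", "p_child_parent_rel"): 0.05,
    ("p_self_efficacy", "p_child_parent_rel"): 0.41,
    ("t_self_efficacy", "p_child_parent_rel"): 0.06,
    ("p_self_control", "p_child_parent_rel"): 0.49,
    ("t_self_control", "p_child_parent_rel"): 0.05,
    ("p_self_esteem", "t_child_teacher_rel"): 0.07,
    ("t_self_esteem", "t_child_teacher_rel"): 0.63,
    ("p_self_efficacy", "t_child_teacher_rel"): 0.11,
    ("t_self_efficacy", "t_child_teacher_rel"): 0.60,
    ("p_self_control", "t_child_teacher_rel"): 0.15,
    ("t_self_control", "t_child_teacher_rel"): 0.61,
    ("p_child_parent_rel", "t_child_teacher_rel"): 0.06,
    ("p_self_esteem", "adversity_index"): -0.09,
    ("t_self_esteem", "adversity_index"): -0.16,
    ("p_self_efficacy", "adversity_index"): -0.05,
    ("t_self_efficacy", "adversity_index"): -0.19,
    ("p_self_control", "adversity_index"): -0.06,
    ("t_self_control", "adversity_index"): -0.13,
    ("p_child_parent_rel", "adversity_index"): -0.07,
    ("t_child_teacher_rel", "adversity_index"): -0.10,
    ("p_self_esteem", "p_sdq_t2"): -0.43,
    ("t_self_esteem", "p_sdq_t2"): -0.17,
    ("p_self_efficacy", "p_sdq_t2"): -0.37,
    ("t_self_efficacy", "p_sdq_t2"): -0.24,
    ("p_self_control", "p_sdq_t2"): -0.38,
    ("t_self_control", "p_sdq_t2"): -0.20,
    ("p_child_parent_rel", "p_sdq_t2"): -0.39,
    ("t_child_teacher_rel", "p_sdq_t2"): -0.16,
    ("adversity_index", "p_sdq_t2"): 0.26,
    ("p_self_esteem", "t_sdq_t2"): -0.15,
    ("t_self_esteem", "t_sdq_t2"): -0.26,
    ("p_self_efficacy", "t_sdq_t2"): -0.18,
    ("t_self_efficacy", "t_sdq_t2"): -0.34,
    ("p_self_control", "t_sdq_t2"): -0.17,
    ("t_self_control", "t_sdq_t2"): -0.34,
    ("p_child_parent_rel", "t_sdq_t2"): -0.14,
    ("t_child_teacher_rel", "t_sdq_t2"): -0.33,
    ("adversity_index", "t_sdq_t2"): 0.13,
    ("p_sdq_t2", "t_sdq_t2"): 0.42,
}

# Per-scale target alphas for item-level generation.
DEFAULT_ALPHAS: dict[str, float] = {
    "p_self_esteem": 0.80, "t_self_esteem": 0.92,
    "p_self_efficacy": 0.78, "t_self_efficacy": 0.93,
    "p_self_control": 0.86, "t_self_control": 0.93,
    "p_child_parent_rel": 0.78, "t_child_teacher_rel": 0.89,
    "p_sdq_t2": 0.83, "t_sdq_t2": 0.87,
    "p_sdq_t1": 0.83, "t_sdq_t1": 0.87,
}

# Gaussian-copula specifications for the raw adversity fields: a loading on
# the adversity latent plus a marginal distribution matched to the reported
# prevalence table (40.3% benefit receipt, 12.9% single parent, 7.2%/2.0%
# adolescent parenthood, education/employment category shares, GHQ clinical
# fraction 39.1% with mean 1.41, one life event per year on average).
DEFAULT_ADVERSITY_THRESHOLDS: dict[str, dict] = {
    "mother_education": {"loading": 0.45, "kind": "categorical",
                         "probs": [0.203, 0.334, 0.216, 0.247], "codes": [1, 2, 3, 4]},
    "father_education": {"loading": 0.45, "kind": "categorical",
                         "probs": [0.112, 0.427, 0.159, 0.303], "codes": [1, 2, 3, 4]},
    "family_employment": {"loading": 0.50, "kind": "categorical",
                          "probs": [0.063, 0.380, 0.399, 0.072, 0.086],
                          "codes": [0, 1, 2, 3, 4]},
    "benefit_receipt": {"loading": 0.50, "kind": "binary", "p": 0.403},
    "n_siblings": {"loading": 0.30, "kind": "categorical",
                   "probs": [0.35, 0.36, 0.20, 0.05, 0.02, 0.012, 0.008],
                   "codes": [0, 1, 2, 3, 4, 5, 6]},
    "single_parent": {"loading": 0.50, "kind": "binary", "p": 0.129},
    "years_separated": {"loading": 0.50, "kind": "categorical",
                        "probs": [0.80, 0.06, 0.045, 0.03, 0.025, 0.02, 0.02],
                        "codes": [0, 1, 2, 3, 4, 5, 6]},
    "mother_age_at_birth": {"loading": 0.35, "kind": "age_at_birth",
                            "mean": 29.0, "p_adolescent": 0.072},
    "father_age_at_birth": {"loading": 0.35, "kind": "age_at_birth",
                            "mean": 32.4, "p_adolescent": 0.020},
    "ghq_total": {"loading": 0.55, "kind": "count", "p_zero": 0.609, "mean": 1.41, "max": 12},
    "lte_count": {"loading": 0.45, "kind": "count", "p_zero": None, "mean": 0.90, "max": 12},
}


@dataclass(frozen=True)
class InjectedEffect:
    """Structural resource effect on an outcome, in standardized (beta) units.

    The outcome is rebuilt as a linear model in the latent z-scores:
    main_beta multiplies the resource, interaction_beta multiplies the
    mean-centred product of the adversity and resource z-scores.  Because the
    outcome is a difficulties score, a beneficial resource has a negative
    main_beta; a protective one has a negative interaction_beta (benefit
    grows with adversity).
    """

    resource: str
    outcome: str
    main_beta: float = 0.0
    interaction_beta: float = 0.0


@dataclass
class GeneratorConfig:
    n_children: int = 474
    seed: int = 0
    target_corr: pd.DataFrame | None = None       # over PRIMARY_NAMES; default = calibration surface
    target_means: dict[str, float] | None = None
    target_sds: dict[str, float] | None = None
    gender_effect_teacher_sdq: float = -0.26      # point-biserial, female coded 1
    gender_effect_parent_sdq: float = -0.05
    female_fraction: float = 0.51
    baseline_stability: float = 0.50              # r(T1, T2) same informant
    baseline_attenuation: float = 0.60            # T1 rows = this x the matching T2 row
    adversity_thresholds: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_ADVERSITY_THRESHOLDS))
    injected_effects: tuple[InjectedEffect, ...] = ()
    item_level: bool = False
    item_alphas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHAS))
    psd_repair_limit: float = 0.05                # largest negative eigenvalue repairable

    def __post_init__(self):
        if self.n_children < 30:
            raise ValueError("n_children must be >= 30")
        if self.target_corr is None:
            self.target_corr = build_target_corr()
        means = {v.name: v.mean for v in ANALYSIS_VARIABLES}
        sds = {v.name: v.sd for v in ANALYSIS_VARIABLES}
        if self.target_means:
            means.update(self.target_means)
        if self.target_sds:
            sds.update(self.target_sds)
        self.target_means = means
        self.target_sds = sds
        if any(sd <= 0 for sd in self.target_sds.values()):
            raise ValueError("all target SDs must be > 0")
        C = self.target_corr
        if list(C.index) != list(C.columns):
            raise ValueError("target_corr must be square with matching labels")
        if not np.allclose(C.values, C.values.T):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(C.values), 1.0):
            raise ValueError("target_corr must have a unit diagonal")
        for eff in self.injected_effects:
            if eff.resource not in C.index:
                raise ValueError(f"unknown resource in injected_effects: {eff.resource!r}")
            if eff.outcome not in OUTCOME_NAMES:
                raise ValueError(f"injected outcome must be one of {OUTCOME_NAMES}, got {eff.outcome!r}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["target_corr"] = self.target_corr.round(10).values.tolist()
        payload["injected_effects"] = [asdict(e) for e in self.injected_effects]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()


def build_target_corr(overrides: dict[tuple[str, str], float] | None = None) -> pd.DataFrame:
    """Correlation matrix over the 11 primary analysis variables."""
    names = list(PRIMARY_NAMES)
    C = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    entries = dict(DEFAULT_CORRELATIONS)
    if overrides:
        entries.update(overrides)
    for (a, b), r in entries.items():
        C.loc[a, b] = r
        C.loc[b, a] = r
    return C


def default_config(n_children: int = 474, seed: int = 0, **kwargs) -> GeneratorConfig:
    return GeneratorConfig(n_children=n_children, seed=seed, **kwargs)


def null_effect_config(n_children: int = 474, seed: int = 0, **kwargs) -> GeneratorConfig:
    """Calibration with every resource-outcome correlation set to zero.

    The adversity-outcome and gender-outcome links are retained; this is the
    null scenario for type-I-error studies of the interaction approach.
    """
    overrides = {}
    for r in RESOURCE_NAMES:
        for o in OUTCOME_NAMES:
            overrides[(r, o)] = 0.0
    return GeneratorConfig(n_children=n_children, seed=seed,
                           target_corr=build_target_corr(overrides), **kwargs)


# ---------------------------------------------------------------------------
# Latent machinery
# ---------------------------------------------------------------------------

def _rng(config: GeneratorConfig, family: str) -> np.random.Generator:
    key = zlib.crc32(family.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def _nearest_psd(C: np.ndarray, repair_limit: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= 1e-10:
        return C
    if vals.min() < -repair_limit:
        raise ValueError(
            f"target correlation matrix is not repairably PSD "
            f"(smallest eigenvalue {vals.min():.4f})"
        )
    warnings.warn(
        f"target correlation matrix repaired to nearest PSD "
        f"(smallest eigenvalue was {vals.min():.2e})",
        stacklevel=3,
    )
    vals = np.clip(vals, 1e-10, None)
    C2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def _extended_corr(config: GeneratorConfig) -> pd.DataFrame:
    """Primary variables + gender latent + baseline SDQ latents."""
    C = config.target_corr.copy()
    names = list(C.columns)
    full = pd.DataFrame(np.eye(len(names) + 3),
                        index=names + ["gender_latent"] + list(BASELINE_NAMES),
                        columns=names + ["gender_latent"] + list(BASELINE_NAMES))
    full.loc[names, names] = C.values

    # Dichotomizing at the female-fraction quantile attenuates a latent
    # correlation by phi(c)/sqrt(p(1-p)); inflate the latent loading so the
    # post-threshold point-biserial hits its target.
    p = config.female_fraction
    c = sps.norm.ppf(1 - p)
    factor = sps.norm.pdf(c) / np.sqrt(p * (1 - p))
    for out, target in (("t_sdq_t2", config.gender_effect_teacher_sdq),
                        ("p_sdq_t2", config.gender_effect_parent_sdq)):
        if out in full.index:
            full.loc["gender_latent", out] = full.loc[out, "gender_latent"] = target / factor

    # Baseline rows: attenuated copies of the matching Time-2 rows, plus the
    # stability and cross-informant links.
    att = config.baseline_attenuation
    for t1, t2 in (("p_sdq_t1", "p_sdq_t2"), ("t_sdq_t1", "t_sdq_t2")):
        for other in names + ["gender_latent"]:
            if other == t2:
                r = config.baseline_stability
            else:
                r = att * full.loc[t2, other]
            full.loc[t1, other] = full.loc[other, t1] = r
    full.loc["p_sdq_t1", "t_sdq_t1"] = full.loc["t_sdq_t1", "p_sdq_t1"] = \
        full.loc["p_sdq_t2", "t_sdq_t2"]
    return full


def _gaussian_product_cov(rho: pd.DataFrame, a: str, pairs_i: tuple[str, str],
                          pairs_j: tuple[str, str]) -> float:
    # Cov(z_a z_b, z_c z_d) = rho_ac rho_bd + rho_ad rho_bc for joint normals.
    (ai, bi), (aj, bj) = pairs_i, pairs_j
    return rho.loc[ai, aj] * rho.loc[bi, bj] + rho.loc[ai, bj] * rho.loc[bi, aj]


def _apply_injections(Z: pd.DataFrame, rho: pd.DataFrame,
                      config: GeneratorConfig, rng: np.random.Generator) -> None:
    """Rebuild injected outcome columns from an explicit structural model.

    The outcome keeps its target correlation with the adversity index and
    gender latent; resource main effects and centred adversity x resource
    interaction effects are set to the injected betas; fresh noise brings the
    variance back to 1.  Interaction terms are orthogonal to all main effects
    under joint normality, so the recovered coefficients equal the injected
    ones up to Monte-Carlo error.
    """
    adv = "adversity_index"
    by_outcome: dict[str, list[InjectedEffect]] = {}
    for eff in config.injected_effects:
        by_outcome.setdefault(eff.outcome, []).append(eff)
    for outcome, effects in by_outcome.items():
        mains = {e.resource: e.main_beta for e in effects}
        inters = {e.resource: e.interaction_beta for e in effects if e.interaction_beta != 0.0}
        b_adv = rho.loc[outcome, adv] - sum(b * rho.loc[r, adv] for r, b in mains.items())
        b_gen = rho.loc[outcome, "gender_latent"]

        terms = {adv: b_adv, "gender_latent": b_gen, **mains}
        main_names = list(terms)
        b = np.array([terms[v] for v in main_names])
        sub = rho.loc[main_names, main_names].to_numpy()
        var = float(b @ sub @ b)
        inter_items = list(inters.items())
        for i, (ri, li) in enumerate(inter_items):
            for rj, lj in inter_items:
                var += li * lj * _gaussian_product_cov(rho, adv, (adv, ri), (adv, rj))
        if var >= 1.0:
            raise ValueError(f"injected effects for {outcome!r} imply variance >= 1 ({var:.3f})")
        sigma_e = np.sqrt(1.0 - var)

        z = sum(bv * Z[v].to_numpy() for v, bv in terms.items())
        for r, lam in inters.items():
            prod = Z[adv].to_numpy() * Z[r].to_numpy() - rho.loc[adv, r]
            z = z + lam * prod
        Z[outcome] = z + sigma_e * rng.standard_normal(len(Z))


# ---------------------------------------------------------------------------
# Raw adversity fields
# ---------------------------------------------------------------------------

def _solve_geometric_ratio(mean: float, kmax: int, p_zero: float | None) -> np.ndarray:
    """Probability vector over 0..kmax with a geometric tail matched to a mean.

    With ``p_zero`` given, P(0) is fixed and the 1..kmax tail is geometric;
    otherwise the whole distribution is geometric from zero.
    """
    ks = np.arange(kmax + 1)

    def dist(r: float) -> np.ndarray:
        w = r ** ks
        if p_zero is not None:
            w = w.copy()
            w[0] = 0.0
            w = w / w.sum() * (1 - p_zero)
            w[0] = p_zero
        else:
            w = w / w.sum()
        return w

    lo_r, hi_r = 1e-6, 1 - 1e-6
    for _ in range(200):
        mid = (lo_r + hi_r) / 2
        if (dist(mid) * ks).sum() < mean:
            lo_r = mid
        else:
            hi_r = mid
    return dist((lo_r + hi_r) / 2)


def _threshold_field(latent: np.ndarray, spec: dict) -> np.ndarray:
    kind = spec["kind"]
    if kind == "binary":
        # adversity-increasing: the top p tail of the latent is flagged
        return (latent > sps.norm.ppf(1 - spec["p"])).astype(int)
    if kind == "categorical":
        probs = np.asarray(spec["probs"], dtype=float)
        probs = probs / probs.sum()
        cuts = sps.norm.ppf(np.cumsum(probs)[:-1])
        idx = np.searchsorted(cuts, latent, side="left")
        return np.asarray(spec["codes"])[idx]
    if kind == "count":
        probs = _solve_geometric_ratio(spec["mean"], spec["max"], spec.get("p_zero"))
        cuts = sps.norm.ppf(np.cumsum(probs)[:-1])
        idx = np.searchsorted(cuts, latent, side="left")
        return idx
    if kind == "age_at_birth":
        # higher adversity latent -> younger parent; the SD is solved so the
        # adolescent-parenthood rate (parent <= 20 at birth) hits its target
        sd = (spec["mean"] - 20.0) / sps.norm.ppf(1 - spec["p_adolescent"])
        return np.clip(np.round(spec["mean"] - sd * latent, 1), 14.0, 55.0)
    raise ValueError(f"unknown adversity field kind {kind!r}")


# ---------------------------------------------------------------------------
# Item-level generation
# ---------------------------------------------------------------------------

def _items_from_totals(totals: np.ndarray, k: int, lo: int, hi: int,
                       alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Allocate integer item responses that sum to each total.

    Between-child variance lives in the shared total; within-child item noise
    is scaled so that Cronbach's alpha approximately equals ``alpha``
    (sigma_e^2 = Var(T) (1-alpha)/k), before rounding and range repairs.
    """
    n = len(totals)
    v_t = totals.var(ddof=1)
    sigma = np.sqrt(max(v_t * (1 - alpha) / k, 1e-12))
    e = rng.normal(0.0, sigma, size=(n, k))
    e -= e.mean(axis=1, keepdims=True)
    items = np.round(totals[:, None] / k + e).astype(int)
    items = np.clip(items, lo, hi)
    # Repair sums: nudge random items within range until each row matches.
    deficits = totals.astype(int) - items.sum(axis=1)
    for i in np.where(deficits != 0)[0]:
        d = deficits[i]
        order = rng.permutation(k)
        j = 0
        while d != 0:
            c = order[j % k]
            if d > 0 and items[i, c] < hi:
                items[i, c] += 1
                d -= 1
            elif d < 0 and items[i, c] > lo:
                items[i, c] -= 1
                d += 1
            j += 1
    return items


def _sdq_items(totals: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """25 SDQ responses per child: 20 difficulty items summing to the total
    plus 5 prosocial items drawn independently."""
    n = len(totals)
    difficulty = _items_from_totals(totals, 20, 0, 2, alpha, rng)
    prosocial = rng.integers(0, 3, size=(n, 5))
    items = np.zeros((n, 25), dtype=int)
    diff_idx = [i for name in ("emotional", "conduct", "hyperactivity", "peer")
                for i in scoring.SDQ_SUBSCALES[name]]
    items[:, diff_idx] = difficulty
    items[:, list(scoring.SDQ_SUBSCALES["prosocial"])] = prosocial
    return items


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    table: pd.DataFrame
    config: GeneratorConfig
    metadata: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
        meta_path = str(path)
        meta_path = meta_path[:-4] + ".meta.json" if meta_path.endswith(".csv") else meta_path + ".meta.json"
        with open(meta_path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort under the configured calibration; deterministic per seed."""
    n = config.n_children
    rho = _extended_corr(config)
    repaired = _nearest_psd(rho.to_numpy(), config.psd_repair_limit)
    rho = pd.DataFrame(repaired, index=rho.index, columns=rho.columns)

    L = np.linalg.cholesky(rho.to_numpy() + 1e-12 * np.eye(len(rho)))
    raw = _rng(config, "analysis_latents").standard_normal((n, len(rho)))
    Z = pd.DataFrame(raw @ L.T, columns=rho.columns)

    if config.injected_effects:
        _apply_injections(Z, rho, config, _rng(config, "injection"))

    table = pd.DataFrame({"child_id": np.arange(1, n + 1)})
    cut = sps.norm.ppf(1 - config.female_fraction)
    table["gender"] = (Z["gender_latent"].to_numpy() > cut).astype(int)

    age_rng = _rng(config, "ages")
    table["child_age"] = np.round(np.clip(age_rng.normal(4.59, 0.33, n), 3.0, 5.0), 2)

    for v in ANALYSIS_VARIABLES:
        x = config.target_means[v.name] + config.target_sds[v.name] * Z[v.name].to_numpy()
        if v.integer:
            x = np.clip(np.round(x), v.lo, v.hi)
        table[v.name] = x

    # Self-concept composites (z-average of self-esteem and self-efficacy).
    for pre in ("p", "t"):
        table[f"{pre}_self_concept"] = scoring.composite_self_concept(
            table[f"{pre}_self_esteem"], table[f"{pre}_self_efficacy"]
        )

    # Raw adversity fields via the Gaussian copula on the adversity latent.
    adv_rng = _rng(config, "adversity_fields")
    z_adv = Z["adversity_index"].to_numpy()
    for name, spec in config.adversity_thresholds.items():
        lam = spec["loading"]
        latent = lam * z_adv + np.sqrt(1 - lam**2) * adv_rng.standard_normal(n)
        table[name] = _threshold_field(latent, spec)
    table["mother_age"] = np.round(table["mother_age_at_birth"] + table["child_age"], 1)
    table["father_age"] = np.round(table["father_age_at_birth"] + table["child_age"], 1)

    if config.item_level:
        item_rng = _rng(config, "items")
        extra: dict[str, np.ndarray] = {}
        scale_cols = [(f"{pre}_{s}", s) for pre in ("p", "t")
                      for s in ("self_esteem", "self_efficacy", "self_control")]
        scale_cols += [("p_child_parent_rel", "child_parent_rel"),
                       ("t_child_teacher_rel", "child_teacher_rel")]
        for col, scale_name in scale_cols:
            _emit_scale_items(extra, table[col].to_numpy(), col,
                              scoring.DEFAULT_SCALES[scale_name],
                              config.item_alphas.get(col, 0.85), item_rng)
        for col in ("p_sdq_t1", "t_sdq_t1", "p_sdq_t2", "t_sdq_t2"):
            items = _sdq_items(table[col].to_numpy(), config.item_alphas.get(col, 0.85), item_rng)
            for j in range(25):
                extra[f"{col}_item_{j + 1}"] = items[:, j]
        _emit_ghq_items(extra, table["ghq_total"].to_numpy(), item_rng)
        _emit_lte_items(extra, table["lte_count"].to_numpy(), item_rng)
        table = pd.concat([table, pd.DataFrame(extra, index=table.index)], axis=1)

    truth = {
        "injected_effects": [asdict(e) for e in config.injected_effects],
        "gender_effect_teacher_sdq": config.gender_effect_teacher_sdq,
    }
    metadata = {
        "seed": config.seed,
        "n_children": n,
        "config_hash": config.config_hash(),
        "true_parameters": truth,
    }
    return SyntheticCohort(table=table, config=config, metadata=metadata)


def _emit_scale_items(extra: dict, totals: np.ndarray, col: str, definition,
                      alpha: float, rng: np.random.Generator) -> None:
    items = _items_from_totals(totals, definition.item_count,
                               definition.item_min, definition.item_max, alpha, rng)
    # Emit raw responses: un-reverse the reverse-coded items so that
    # score_sum_scale reproduces the stored total.
    rev = list(definition.reverse_items)
    if rev:
        items = items.copy()
        items[:, rev] = definition.item_min + definition.item_max - items[:, rev]
    for j in range(definition.item_count):
        extra[f"{col}_item_{j + 1}"] = items[:, j]


def _emit_ghq_items(extra: dict, totals: np.ndarray, rng: np.random.Generator) -> None:
    totals = totals.astype(int)
    items = np.zeros((len(totals), 12), dtype=int)
    for i, t in enumerate(totals):
        flagged = rng.choice(12, size=t, replace=False)
        items[i, flagged] = rng.integers(2, 4, size=t)
        rest = np.setdiff1d(np.arange(12), flagged)
        items[i, rest] = rng.integers(0, 2, size=len(rest))
    for j in range(12):
        extra[f"ghq_item_{j + 1}"] = items[:, j]


def _emit_lte_items(extra: dict, counts: np.ndarray, rng: np.random.Generator) -> None:
    counts = counts.astype(int)
    items = np.zeros((len(counts), 12), dtype=int)
    for i, c in enumerate(counts):
        items[i, rng.choice(12, size=c, replace=False)] = 1
    for j in range(12):
        extra[f"lte_event_{j + 1}"] = items[:, j]


# ---------------------------------------------------------------------------
# Calibration check
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    max_corr_deviation: float
    max_mean_deviation_sd: float
    max_sd_ratio_deviation: float
    worst_pair: tuple[str, str]
    passed: bool
    pairs: pd.DataFrame = field(repr=False, default=None)


def check_calibration(cohort: SyntheticCohort, config: GeneratorConfig,
                      tolerance: float = 0.05) -> CalibrationReport:
    """Compare a generated cohort's empirical moments against its targets.

    Reports the maximum absolute pairwise-correlation deviation (the pass /
    fail criterion), plus mean deviations in SD units and SD-ratio
    deviations, which absorb the effects of rounding and range clipping
    (reported, not corrected).  Outcome columns rebuilt by injected effects
    are excluded from the correlation comparison.
    """
    if cohort.metadata.get("config_hash") != config.config_hash():
        raise ValueError("cohort was not generated by this configuration")
    skip = {e.outcome for e in config.injected_effects}
    names = [v for v in config.target_corr.columns if v not in skip]
    emp = cohort.table[names].corr()
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({"var_a": a, "var_b": b,
                         "target": config.target_corr.loc[a, b],
                         "empirical": emp.loc[a, b],
                         "deviation": emp.loc[a, b] - config.target_corr.loc[a, b]})
    pairs = pd.DataFrame(rows)
    worst = pairs.loc[pairs["deviation"].abs().idxmax()]
    mean_devs = []
    sd_devs = []
    for v in names:
        mu, sd = config.target_means[v], config.target_sds[v]
        mean_devs.append(abs(cohort.table[v].mean() - mu) / sd)
        sd_devs.append(abs(cohort.table[v].std(ddof=1) / sd - 1.0))
    max_corr = float(pairs["deviation"].abs().max())
    return CalibrationReport(
        max_corr_deviation=max_corr,
        max_mean_deviation_sd=float(max(mean_devs)),
        max_sd_ratio_deviation=float(max(sd_devs)),
        worst_pair=(worst["var_a"], worst["var_b"]),
        passed=max_corr < tolerance,
        pairs=pairs,
    )
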