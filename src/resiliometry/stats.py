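"""Shared statistical engine for the resilience analyses.

Everything downstream (the moderated-regression, residuals, multiple-groups
and person-centred approaches) is built from the primitives here: blockwise
hierarchical OLS with standardized coefficients, reverse-coded standardized
residuals, RMS-pooled Cohen's d, first-order partial correlation, the
unpooled two-proportion z test, deterministic tertile splits, a
covariate-adjusted MANOVA (Wilks' lambda via SSCP decomposition with Rao's F
approximation), and the Pearson chi-square test of independence.

Conventions
-----------
* Standardized betas come from fitting on z-scored variables (ddof=1), not
  from post-hoc rescaling of raw coefficients.
* All tests are two-tailed at alpha = .05 unless stated otherwise.
* Complete-case inputs are assumed; callers are responsible for filtering
  and logging exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

ALPHA = 0.05

__all__ = [
    "ALPHA",
    "StepResult",
    "StepwiseModelResult",
    "ContrastResult",
    "ManovaResult",
    "zscore",
    "hierarchical_regression",
    "reverse_coded_residuals",
    "cohens_d",
    "partial_correlation",
    "two_proportion_z",
    "tertile_split",
    "mancova",
    "chi_square_independence",
]


def zscore(x, ddof: int = 1) -> np.ndarray:
    """Sample z-score with the n-1 denominator used throughout the analyses."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Hierarchical (blockwise) regression
# ---------------------------------------------------------------------------

@dataclass
class StepResult:
    """One cumulative block of a hierarchical regression."""

    step: int
    variables: tuple[str, ...]          # all predictors in the model at this step
    entered: tuple[str, ...]            # predictors added at this step
    betas: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    delta_r_squared: float
    delta_f: float
    delta_f_df: tuple[int, int]
    delta_f_pvalue: float


@dataclass
class StepwiseModelResult:
    """Full trace of a blockwise OLS fit on standardized variables."""

    outcome: str
    n: int
    steps: list[StepResult]

    @property
    def final(self) -> StepResult:
        return self.steps[-1]

    @property
    def r_squared(self) -> float:
        return self.final.r_squared

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for v in s.variables:
                rows.append(
                    {
                        "step": s.step,
                        "variable": v,
                        "beta": s.betas[v],
                        "p": s.pvalues[v],
                        "r_squared": s.r_squared,
                        "delta_r_squared": s.delta_r_squared,
                        "delta_f": s.delta_f,
                        "delta_f_p": s.delta_f_pvalue,
                    }
                )
        return pd.DataFrame(rows)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        cum_rank = 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == cum_rank:
                aliased.append(names[j])
            cum_rank = r
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    blocks: Sequence[Sequence[str]],
    standardize: bool = True,
) -> StepwiseModelResult:
    """Blockwise OLS with per-step R², ΔR² and the ΔF increment test.

    Each block adds predictors cumulatively; ΔF at step k for q added terms is
    (ΔR²/q) / ((1 - R²_k) / (n - p_k - 1)) with p_k predictors in the step-k
    model.  With ``standardize`` the outcome and every predictor are z-scored
    first, so coefficients are standardized betas (for a single predictor the
    beta equals the Pearson correlation).
    """
    if not blocks or any(len(b) == 0 for b in blocks):
        raise ValueError("each block must name at least one predictor")
    all_vars = [outcome] + [v for b in blocks for v in b]
    if len(set(all_vars)) != len(all_vars):
        dupes = sorted({v for v in all_vars if all_vars.count(v) > 1})
        raise ValueError(f"duplicated variables across blocks: {dupes}")
    df = data[all_vars].astype(float)
    if df.isna().any().any():
        raise ValueError("missing values in analysis variables; complete cases required")
    n = len(df)
    total_p = sum(len(b) for b in blocks)
    if n <= total_p + 1:
        raise ValueError(f"n={n} too small for {total_p} predictors")
    if standardize:
        df = df.apply(zscore, raw=False)

    y = df[outcome].to_numpy()
    steps: list[StepResult] = []
    prev_r2 = 0.0
    current: list[str] = []
    for k, block in enumerate(blocks, start=1):
        current = current + list(block)
        X = df[current].to_numpy()
        _check_rank(np.column_stack([np.ones(n), X]), ["const"] + current)
        model = sm.OLS(y, sm.add_constant(X)).fit()
        r2 = float(model.rsquared)
        dr2 = r2 - prev_r2
        q = len(block)
        df_den = n - len(current) - 1
        if 1.0 - r2 <= 0:
            delta_f = math.inf
            p_delta = 0.0
        else:
            delta_f = (dr2 / q) / ((1.0 - r2) / df_den)
            p_delta = float(sps.f.sf(delta_f, q, df_den))
        betas = {v: float(model.params[i + 1]) for i, v in enumerate(current)}
        pvals = {v: float(model.pvalues[i + 1]) for i, v in enumerate(current)}
        steps.append(
            StepResult(
                step=k,
                variables=tuple(current),
                entered=tuple(block),
                betas=betas,
                pvalues=pvals,
                r_squared=r2,
                delta_r_squared=dr2,
                delta_f=delta_f,
                delta_f_df=(q, df_den),
                delta_f_pvalue=p_delta,
            )
        )
        prev_r2 = r2
    return StepwiseModelResult(outcome=outcome, n=n, steps=steps)


# ---------------------------------------------------------------------------
# Resilience residuals
# ---------------------------------------------------------------------------

def reverse_coded_residuals(outcome, predictor) -> np.ndarray:
    """Reverse-coded standardized residuals of a difficulties outcome on adversity.

    Residuals from the simple regression of ``outcome`` on ``predictor`` are
    standardized to mean 0 / SD 1 and multiplied by -1, so that a positive
    score marks a child with fewer difficulties than adversity predicts
    (greater resilience).  The scores are orthogonal to the predictor by
    construction.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and predictor must be equal-length vectors")
    if len(y) < 10:
        raise ValueError("need at least 10 complete pairs")
    if x.std(ddof=1) == 0:
        raise ValueError("predictor has zero variance")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(1.0, y.std(ddof=1)):
        # outcome is an exact linear function of the predictor
        return np.zeros_like(resid)
    return -(resid - resid.mean()) / sd


# ---------------------------------------------------------------------------
# Effect sizes and elementary tests
# ---------------------------------------------------------------------------

def cohens_d(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    pooling: str = "rms",
) -> float:
    """Standardized mean difference between two groups.

    ``pooling='rms'`` (default) uses the root-mean-square of the two SDs,
    d = (m_a - m_b) / sqrt((sd_a² + sd_b²)/2); ``pooling='df'`` uses the
    df-weighted pooled SD.  The RMS form is the one that reproduces the
    planned-contrast effect sizes reported for the adaptation groups.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if pooling == "rms":
        pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    elif pooling == "df":
        pooled = math.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return (mean_a - mean_b) / pooled


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z from three bivariate correlations.

    This is also the correlation between the two reverse-coded residual
    vectors obtained by partialling z out of x and of y.
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if abs(r_xz) == 1.0 or abs(r_yz) == 1.0:
        raise ValueError("undefined when a conditioning correlation is +/-1")
    det = 1 + 2 * r_xy * r_xz * r_yz - r_xy**2 - r_xz**2 - r_yz**2
    if det < -1e-10:
        raise ValueError("implied 3x3 correlation matrix is not positive semi-definite")
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int, pooled: bool = False):
    """z test for the difference of two independent proportions.

    Defaults to the unpooled standard error
    sqrt(p1(1-p1)/n1 + p2(1-p2)/n2).  Returns (z, two-tailed p).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("counts must satisfy 0 <= k <= n with n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    if p1 in (0.0, 1.0) and p2 in (0.0, 1.0):
        raise ValueError("degenerate proportions in both groups")
    if pooled:
        p = (k1 + k2) / (n1 + n2)
        se = math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    else:
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = (p1 - p2) / se
    return z, 2 * sps.norm.sf(abs(z))


def tertile_split(values) -> np.ndarray:
    """Split a vector into low/mid/high thirds at the empirical 1/3 and 2/3 quantiles.

    Ties at a boundary are all assigned to the lower stratum (v <= q1 is low,
    q1 < v <= q2 is mid), which makes the split deterministic.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 9:
        raise ValueError("need a vector of at least 9 values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if len(np.unique(v)) < 3:
        raise ValueError("fewer than 3 distinct values; tertiles undefined")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    labels = np.where(v <= q1, "low", np.where(v <= q2, "mid", "high"))
    return labels


# ---------------------------------------------------------------------------
# MANCOVA (Wilks' lambda via SSCP decomposition, Rao's F)
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    wilks_lambda: float
    f_value: float
    df1: float
    df2: float
    pvalue: float
    partial_eta_squared: float
    n_groups: int
    n_dvs: int
    univariate: pd.DataFrame = field(repr=False)


def _resid_sscp(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R


def mancova(dv_matrix, group_labels, covariate=None) -> ManovaResult:
    """Covariate-adjusted one-way MANOVA.

    The hypothesis SSCP for the group factor is obtained by comparing residual
    SSCP matrices of the full model (intercept + covariates + group dummies)
    and the reduced model (intercept + covariates).  Wilks' lambda =
    det(E)/det(E+H), converted to an F statistic by Rao's approximation, with
    multivariate partial eta² = 1 - lambda^(1/s).  Univariate ANCOVA F tests
    per DV carry Bonferroni-adjusted p values (family = number of DVs).
    """
    Y = np.asarray(dv_matrix, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(group_labels)
    n, p = Y.shape
    if len(groups) != n:
        raise ValueError("group labels do not match DV rows")
    levels = [g for g in pd.unique(groups)]
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    if (counts <= p).any():
        small = counts[counts <= p].index.tolist()
        raise ValueError(f"groups with n <= number of DVs: {small}")

    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    parts = [np.ones((n, 1))]
    if covariate is not None:
        C = np.asarray(covariate, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        parts.append(C)
    X_red = np.column_stack(parts)
    X_full = np.column_stack(parts + [dummies])

    E = _resid_sscp(Y, X_full)
    H = _resid_sscp(Y, X_red) - E
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_t <= 0:
        raise ValueError("singular within-group SSCP matrix")
    lam = float(np.exp(logdet_e - logdet_t))

    q = k - 1
    v = n - np.linalg.matrix_rank(X_full)
    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    m = v - (p - q + 1) / 2.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f_value = (1 - lam_s) / lam_s * df2 / df1
    pvalue = float(sps.f.sf(f_value, df1, df2))
    eta = 1.0 - lam_s

    rows = []
    for j in range(p):
        h, e = H[j, j], E[j, j]
        f_uni = (h / q) / (e / v)
        p_uni = float(sps.f.sf(f_uni, q, v))
        rows.append(
            {
                "dv": j,
                "F": f_uni,
                "df1": q,
                "df2": v,
                "p": p_uni,
                "p_bonferroni": min(1.0, p_uni * p),
                "partial_eta_squared": h / (h + e),
                "significant": p_uni * p < ALPHA,
            }
        )
    return ManovaResult(
        wilks_lambda=lam,
        f_value=f_value,
        df1=df1,
        df2=df2,
        pvalue=pvalue,
        partial_eta_squared=eta,
        n_groups=k,
        n_dvs=p,
        univariate=pd.DataFrame(rows),
    )


def chi_square_independence(table):
    """Pearson chi-square test of independence on an r x c contingency table.

    Returns (chi2, df, p).  No continuity correction (matches the df=(r-1)(c-1)
    large-sample test).
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class ContrastResult:
    """Planned comparison between two adaptation groups on one resource."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    mean_difference: float
    d: float
    statistic: float
    pvalue: float
    p_adjusted: float
    significant: bool
    test: str = "t"
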