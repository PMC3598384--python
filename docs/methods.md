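# Methods

This note records the statistical conventions, the synthetic-data model and
the numerical choices behind `resiliometry`, in the spirit of a package
methods appendix: everything here is what the code does, not an empirical
claim beyond what the test suite and `scripts/acceptance.py` compute.

## The data model

One row per child. Variables carry an informant prefix (`p_` parent, `t_`
teacher): Time-1 resource scales (self-esteem 14–70, self-efficacy 9–36,
self-control 8–40, child–parent and child–teacher relationship quality
15–75), the derived self-concept composites, SDQ total difficulties (0–40)
at Time 1 and Time 2, `gender` (female = 1), the continuous
`adversity_index`, and the raw family-adversity fields from which the index
can be rebuilt. All analyses are complete-case; exclusion counts are logged
in the run manifest, and no missing-item proration is performed anywhere in
scoring.

## Scoring conventions

* **SDQ.** Total difficulties is the sum of the emotional, conduct,
  hyperactivity and peer subscales; the prosocial subscale is excluded.
  Clinical flags use strict inequalities — total **> 14** (parent) or
  **> 12** (teacher) — and are configurable.
* **GHQ-12.** Binary 0-0-1-1 scoring: a response of 2 or 3 on the 0–3 scale
  contributes one point; a total ≥ 1 flags clinical-level distress.
* **LTE-Q.** Count of the 12 binary family life-event categories.
* **Summed scales.** Reverse-coded items are flipped within the item range
  before summation. The relationship short forms default to reversing items
  8–15 (the conflict block) so that higher totals mean better-quality
  relationships; the exact published reversal set is not stated anywhere we
  could anchor to, so this is a documented configuration default, not an
  assertion. Likewise the self-control response coding (1–5, totals 8–40)
  is a documented default; a 0–4 coding is expressible through
  `ScaleDefinition`.
* **Self-concept composite.** Parent- and teacher-reported self-esteem and
  self-efficacy correlate strongly enough to be statistically inseparable,
  so each informant's pair is combined as the mean of their within-sample
  z-scores. The composite has mean 0 and SD √((1+r)/2) — about 0.91
  (parent) and 0.96 (teacher) at the calibration correlations.
* **Standardization** always uses the analysis-sample mean and the n−1 SD.

## The cumulative adversity index

Eleven indicators in five groups (SES ×5, separation ×2, early parenthood
×2, parental distress ×1, life events ×1), each oriented so higher = more
adversity (education ordinals are coded with higher = lower attainment for
this reason). Construction: z-score each indicator → average z-scores
within each multi-indicator group → z-score the five group scores → sum.
The total therefore has sample mean 0 by construction while its SD is
data-dependent and reported, never forced. The alternative order (average
raw indicators, then standardize the group) is implemented behind the
`order` switch because the construction is ambiguous at the level of
published description; standardize-then-average is the default since it
keeps each indicator's contribution scale-free. Equal group weights are
fixed by default (per-group weights exist as an experimental option).
Standardization constants can be frozen and reused so that sensitivity
reruns keep the full-sample Time-1 scaling. A VIF screen
(`collinearity_screen`, flag at VIF > 10) guards against entering
near-duplicate indicators.

## The four approaches

**Approach 1 — moderated regression.** All variables (including the binary
gender covariate) are z-scored, so coefficients are standardized betas and
centring is automatic; product terms are products of z-scores, left
unrescaled so a fitted interaction beta is directly comparable to a
structural interaction coefficient. ΔF for a block of q predictors at step
k is (ΔR²/q) / ((1−R²ₖ)/(n−pₖ−1)). Simple slopes are evaluated at moderator
mean ± 1 SD. Classification of a moderated effect requires **both** p < .05
on the product term **and** a benefit difference across ±1 SD of adversity
(|2·b_int| in beta units) of at least the differential-effect threshold
(default .15, shared with Approach 3). The magnitude requirement is
deliberate: in large samples trivially small interactions reach
significance, and a label that flips between "promotive" and "protective"
on a |β| = .02 product term would be noise. With the difficulties outcome,
benefit at adversity a is −(b_res + a·b_int); benefit growing with
adversity is *protective*, shrinking but still positive is
*protective-reactive*, absent under high adversity is *reactive*.

**Approach 2 — residuals.** Reverse-coded standardized residuals of Time-2
difficulties on the adversity index (mean 0, SD 1, orthogonal to adversity
by construction; positive = resilient). Exact zeros — possible only on
degenerate data — are counted as vulnerable and reported. The residuals are
regressed on gender (step 1) and the four informant-matched resources
(step 2). The single-resource beta equals (up to sign) the first-order
partial correlation of resource and outcome given adversity, which the test
suite verifies numerically.

**Approach 3 — multiple groups.** Tertile split of the adversity index
(cut points at the empirical 1/3 and 2/3 quantiles; boundary ties go to the
lower stratum, making the split deterministic). The step-2 model is
refitted inside the low and high tertiles; by default the whole-sample
residual scores are reused (the residual is a property of the child, not of
the stratum), with within-stratum regeneration available behind a flag.
Labels are a pure function of the two betas, their significance and the Δβ
threshold: |Δβ| < .15 with a significant effect → promotive; β_high − β_low
≥ .15 → protective; β_low − β_high ≥ .15 → reactive (protective-reactive if
the high-stratum effect remains significantly positive). The .15 default
sits below the smallest between-stratum difference conventionally
interpreted as differential (≈ .17) and is configurable. No formal test of
beta equality is performed — the comparison is descriptive by design.

**Approach 4 — person-centred.** Adversity and SDQ tertiles are crossed;
children in a middle tertile on either variable are Unclassified and
excluded (an `include_middle` variant collapses to a 2×2). Because of the
cut-off method, Resilient and Competent children are identical on the SDQ
tertile and Resilient and Maladaptive on the adversity tertile — asserted
as a containment property in the tests. Group structure is checked with the
Pearson χ² on the full 3×3 tertile table (df = 4) and an **unpooled**
two-proportion z comparing the low-difficulties share of the low- vs
high-adversity tertiles (the unpooled form is the one consistent with the
reference value the acceptance suite reproduces; the pooled form is
available). Group comparison: MANCOVA with gender covariate — hypothesis
SSCP from full/reduced residual SSCP matrices, Wilks' Λ = det(E)/det(E+H),
Rao's F approximation, multivariate partial η² = 1 − Λ^(1/s) — with
Bonferroni-adjusted univariate tests (family = number of resources).
Levene's test (median-centred, α = .05) per resource triggers a
nonparametric fallback (Kruskal–Wallis omnibus, Mann–Whitney contrasts).
Three planned contrasts per resource (Resilient–Maladaptive,
Resilient–Competent, Competent–HighlyVulnerable), Bonferroni-adjusted
within the triplet. Effect sizes are **RMS-pooled** Cohen's d,
d = (m₁−m₂)/√((s₁²+s₂²)/2), computed on raw (unadjusted) group means; the
df-weighted pooling is available but is not the default because the RMS
form is the one that reproduces the reference contrast values. The pattern
label uses the canonical two-contrast logic: a resource separating the
high-adversity pair *and* the low-adversity pair is promotive; only the
high-adversity pair, protective; only the low-adversity pair, reactive.
The Resilient–Competent contrast is reported but not load-bearing, because
with large samples even the small selection-induced difference between
those groups becomes significant and would make the label sample-size
dependent in a way the taxonomy does not intend.

## Synthetic cohort generator

The generator exists so that every stage is testable end to end and so that
method behaviour can be studied against known truth.

* **Continuous analysis variables** are a latent multivariate normal
  matched to a target correlation surface (defaults: the published pairwise
  correlations among the eleven primary variables), rescaled to target
  means/SDs, rounded and clipped to legal scale ranges. Clipping and
  rounding attenuate moments slightly (most visibly the SD of the
  zero-floored SDQ scores); `check_calibration` reports these deviations
  rather than silently correcting them, and passes/fails on the maximum
  absolute pairwise correlation deviation (default tolerance .05, sized for
  n ≥ 5000 from the Fisher-z sampling error).
* **Gender** is a thresholded latent (51% female). Dichotomization
  attenuates a latent correlation by φ(c)/√(p(1−p)), so the latent loading
  is inflated to hit the target *point-biserial* effects on the outcomes
  (−.26 teacher, −.05 parent).
* **Raw adversity fields** come from a Gaussian copula on the adversity
  latent: each field is λ·z_adv + √(1−λ²)·ε thresholded to its target
  marginal (benefit receipt 40.3%, single parent 12.9%, 3+ siblings 8.9%,
  adolescent mother/father 7.2%/2.0%, education and employment category
  shares, GHQ with 39.1% ≥ 1 and mean 1.41 via a geometric tail, life
  events mean 0.90). Loadings are moderate (.3–.55) so the rebuilt
  composite tracks, but does not duplicate, the generated index.
* **Baseline (Time-1) SDQ** uses the retained-sample means (8.47 parent,
  5.28 teacher) with SDs solved so the Time-1 clinical rates equal 5.3% /
  5.9%; stability r(T1,T2) = .50 is a generator choice in the typical range
  for a two-year SDQ interval, and the remaining T1 correlations are
  attenuated copies (×.6) of the matching T2 rows. These values shape the
  sensitivity-analysis scenario and are configurable.
* **Injected effects** rebuild an outcome column from an explicit
  structural model in latent z-units: main betas on resources, an
  interaction beta on the mean-centred adversity × resource product, the
  target adversity and gender links preserved, and fresh noise restoring
  unit variance (the variance bookkeeping uses the Gaussian product-moment
  identities; over-specified effects with implied variance ≥ 1 are
  rejected). Interaction terms are orthogonal to all main effects under
  joint normality, so downstream regressions recover the injected
  coefficients up to Monte-Carlo error. A convenience `null_effect_config`
  zeroes every resource–outcome correlation for type-I-error studies.
* **Item-level generation** (optional) allocates integer item responses
  summing exactly to each child's total, with within-child noise variance
  Var(T)(1−α)/k so Cronbach's α approximately matches the per-scale target;
  GHQ and LTE items are drawn consistent with their totals. Items exist to
  exercise the scoring layer — all analyses run on totals.
* **Randomness** is split into named per-family streams (analysis latents,
  injection noise, gender/ages, adversity fields, items) derived from the
  seed, so enabling one family does not perturb another. The same seed and
  config reproduce a cohort byte-identically, and the sidecar metadata
  (seed, config hash, injected truth) suffices to regenerate it.

What the generator does **not** emulate: attrition and missingness,
preschool-level clustering, floor/ceiling item response styles, and any
joint structure among the eleven adversity indicators beyond what the
single adversity latent induces (their full joint distribution is not
identifiable from published marginals). Passing tests on synthetic cohorts
therefore demonstrate correctness of the machinery and behaviour under the
calibrated correlation surface — not validity on any particular real
cohort.

## Scenario and error-rate studies (test-suite conditions)

The recovery studies run at n = 5000 per cohort, 100 seeds, which keeps the
full suite in the minutes range while leaving Monte-Carlo error on a beta
around .014. The *promotive* scenario injects a main effect of −.25 on one
resource. The *protective* scenario fixes the expected resource effect
inside the low-adversity tertile at exactly zero — main = −interaction ×
E[z | top third] with E[z | top third] = 3φ(Φ⁻¹(2/3)) ≈ 1.091 — which is
the definition of a purely protective factor (benefit only under high
adversity) rather than a tuned quantity. The type-I study uses the
null-effect generator at the reference cohort size (n = 474) over 200
seeds and checks the per-term interaction false-positive rate against a
99.9% binomial band around α = .05.

## Numerical details and degenerate inputs

* OLS is delegated to statsmodels; rank deficiency is detected before
  fitting and reported with the aliased column names.
* An outcome that is an exact linear function of the predictor yields
  all-zero residuals (guarded against blow-up from standardizing numerical
  noise).
* Tertile splits need ≥ 3 distinct values and ≥ 9 observations; subgroup
  models enforce a minimum stratum size (default 30).
* The extended latent correlation matrix (primaries + gender latent +
  baseline rows) may drift slightly non-PSD after user overrides; eigen-
  clipping repair is applied with a warning up to a configurable limit
  (default smallest eigenvalue ≥ −.05), beyond which generation fails
  naming the offending eigenvalue.
* MANCOVA falls back to s = 1 in Rao's approximation when p²+q²−5 ≤ 0, and
  errors on singular within-group SSCP matrices; with one DV it reduces
  exactly to the (AN)COVA F.
* All tests are two-tailed at α = .05; Bonferroni correction is applied
  only within the MANCOVA univariate family and within each planned-
  contrast triplet.

## Known limitations

* Effect-pattern labels near the Δβ threshold are inherently unstable
  under resampling; the threshold is configurable and reported in every
  manifest.
* The Approach-4 labels depend on group sizes through contrast power; this
  is intrinsic to the person-centred taxonomy and documented rather than
  patched.
* The generator's copula ties all adversity fields to one latent; real
  cohorts have richer dependence (e.g. education–employment links beyond a
  shared factor).
* `simple_slopes` emits plot coordinates but no figures; plotting is out of
  scope.
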