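# Methods

This note documents the statistical machinery the package implements, the
choices made where the methodology leaves room, and what the synthetic
cohorts do and do not establish.

## Scoring model

The t-FAB comprises four tasks scored 0–3. Subtest 1 (Conceptualization +
Mental flexibility) is shared between the motor and verbal versions;
subtest 2 exists per version (Sensitivity to interference + Inhibitory
control). Totals are 0–12, subtests 0–6. Records with missing tasks are
scored partially: only the score families whose tasks are present are
reported.

## Demographic adjustment

`AS = RS + Σ β·(f(x) − f̄)` with `β` the **negated** OLS slope and `f̄`
the cohort mean of the *transformed* covariate (the published centering
constant 167 162.855491 is the mean of age³, not the cube of the mean
age). Adjusted scores are an open regression scale and are deliberately
not clamped to [0, 12]; they are reported at 2 decimals while the
unrounded value is retained internally.

Stepwise selection is implemented as forward entry: at each step every
not-yet-entered covariate (age, education, sex) is screened over its
candidate transforms (age: identity/square/cube; education:
identity/log₁₀/ln/1-x; sex: 0/1 indicator), the pair with the largest R²
gain is tested, and it enters iff its slope p-value is below
`entry_alpha` (default 0.05). Whether the original procedure was forward,
backward or bidirectional is not specified by the source methodology;
forward entry reproduces the expected selection pattern (education on all
scores, age only on motor-response scores) and is the documented default.
log₁₀ and ln are perfectly collinear, so ties are broken by candidate
order (log₁₀ first); the near-collinear education transforms
(log₁₀ vs reciprocal) are empirically distinguishable only at large n,
which is why derived equations may legitimately pick a different member of
that family on small cohorts — the fitted correction is virtually
identical.

## Tolerance limits and Equivalent Scores

Outer/inner tolerance limits are exact one-sided non-parametric bounds on
the worst-5% region at 95% confidence: `rank_outer` is the largest r with
P[Bin(n, 0.05) ≥ r] ≥ 0.95 and `rank_inner` the smallest s with
P[Bin(n, 0.05) ≤ s−1] ≥ 0.95, computed by exact binomial CDF enumeration
(no normal approximation). No outer rank exists below n = 59
(1 − 0.95⁵⁸ < 0.95 ≤ 1 − 0.95⁵⁹); small cohorts yield a model flagged
`no_outer_TL` instead of a silent default.

ES bands on the ranked adjusted scores: ES 0 at or below the outer limit;
ES 4 at or above the sample median; ES 1–3 partition the interval in
between, with the two interior cut points at the order statistics nearest
to n·p for p = 0.1086, 0.2054 — the values of Φ at the interior points of
an equal-width partition of [z = −1.645, z = 0]. The exact interior rule
used for the published tables is delegated by the source to its normative
references and cannot be re-derived without the original data, so the
scheme here is explicit and configurable rather than asserted as
identical; the published boundaries themselves ship verbatim as the
built-in model. Band membership rounds AS to 2 decimals first, because the
printed bands are closed 2-decimal intervals (e.g. 8.08–9.45); rounding
(not truncation) is the documented choice. Ties in ranking use a stable
sort keyed by participant id, making derivation byte-reproducible.

## Psychometrics

* **Correlations** — Pearson when both variables have |skewness| < 1 and
  |excess kurtosis| < 3, Spearman otherwise; pairwise deletion;
  significance flags at Bonferroni-adjusted α/family_size, with
  family_size an explicit argument (the original comparison counts are not
  always recoverable).
* **ICC** — default two-way random effects, absolute agreement, single
  rater (ICC(2,1)); the mixed/consistency variant is available. The model
  choice is not stated in the source; absolute agreement is the
  conservative default for inter-rater designs. Estimates and F-based CIs
  come from pingouin's variance-components table.
* **PCA** — eigendecomposition of the task correlation matrix;
  eigenvalue > 1 retention; loadings = eigenvector·√λ₁ sign-fixed so
  their sum is positive.
* **TOST** — equivalence bounds are standardized (dz) and converted to raw
  units via the SD of the paired differences; both one-sided tests use the
  central t distribution with n−1 df; a conventional paired t-test is
  reported alongside. The companion sample-size formula is the normal
  approximation `ceil[(z₁₋α + z₁₋(1−power)/2)² / dz²]` (the
  parametrization that yields the designed N = 52); the exact central-t
  iteration is available behind a flag and is never smaller. Note the
  exact power of the t-based TOST at the normal-approximation n is
  slightly below nominal (0.9409 at n = 52 for 95% nominal power) — an
  inherent property of the approximation, visible in the Monte-Carlo test.
* **Regression sample size** — smallest denominator df v with noncentral
  F(u, v, λ) power ≥ target. The noncentrality convention is explicit
  (`λ = f²(u+v+1)` by default, `λ = f²v` optional) because published
  calculators differ; at (f² = 0.05, u = 3, α = 0.05, power = 0.95)
  the two conventions give N = 348 and N = 352 respectively.

## Diagnostics

AUC is the tie-corrected Mann–Whitney estimator after orienting the
marker so cases tend high; the default orientation treats **lower** scores
as case-like, since impairment lowers t-FAB scores. Standard errors use
DeLong's structural components (midrank placements, ties contribute ½);
Hanley–McNeil is retained as an option for comparability with older
calculators. The Obuchowski binormal-variance design uses one-sided α by
default — the convention that reproduces the published (19 cases,
190 controls) pair at AUC 0.7, κ = 10, 90% power; two-sided is available
and strictly larger.

## Synthetic cohorts

The normative generator samples demographics from the published
age × education × sex stratum counts (ages/educations uniform integers
within each band), builds a continuous propensity per version total using
the published adjustment equations as the generating truth (negated, so
the published correction removes the effect exactly), adds correlated
Gaussian noise (`latent_sd` 1.3, between-version correlation 0.7 — chosen
to match the observed total-score spread ≈1.2–1.5 and the fact that the
two versions share subtest 1), and discretizes by round-then-truncate to
[0, 12]. The ceiling anchor is calibrated per outcome by deterministic
bisection on the seeded sample so that the fraction at 12 hits the targets
0.358 (motor) / 0.393 (verbal) within ±0.02. Subtest 1 is carved out of
the two totals deterministically near its typical ~48% share, and each
subtest total k splits into tasks (min(3, k), remainder).

What this emulates: marginal score distributions with realistic ceiling
mass, the direction and approximate size of the demographic effects, the
stratification, and group-level clinical means/SDs. What it does not:
item-level response processes, companion-test joint distributions, or the
true (unpublished) within-person motor/verbal correlation — the latter is
a free parameter. Passing tests therefore establish correctness of the
*machinery* (selection, limits, thresholds, AUC, power), not empirical
claims about real cohorts; the data-dependent published statistics (ICCs,
PCA variance shares, empirical AUCs, ES boundaries) are deliberately not
asserted as targets.

**Parameter recovery regime.** The end-to-end recovery checks (refit the
published equations from a generated cohort within 10% at n = 5000) run
with a low ceiling target (0.05) and latent_sd 1.0: OLS recovery is a
property of the correctly-specified linear-Gaussian regime, and heavy
censoring at the ceiling attenuates slopes — by design, not by defect.
Under the default 36–39% ceiling the generator is validated by the weaker
sign-and-selection contract instead.

## Numerical conventions and limitations

* Rounding is half-away-from-zero at 2 decimals (`Decimal` quantize), the
  convention that reproduces every printed grid cell.
* Problem sizes in the test-suite Monte-Carlo checks (10⁴ TOST
  replicates, n = 5000 recovery cohorts, exhaustive tolerance-rank
  enumeration to n = 2000) were chosen as the smallest sizes at which the
  targeted tolerances are statistically meaningful.
* No parametric (Gaussian z-score) norming alternative and no
  longitudinal/reliable-change norms are provided.
* Demographic coverage outside age 18–96 / education 4–23 flags results
  as extrapolated rather than refusing to score.
* The published model has no sex term, but sex is a first-class candidate
  predictor for user-derived norms.
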