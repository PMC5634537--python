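# Methods

## Two-list capture–recapture

Deaths are cross-classified by membership in two incomplete lists: a
news-media registry (list 1) and the set of NVSS records carrying a
legal-intervention ICD-10 code (list 2). Within stratum *s* (calendar
quarter of death) the observed cells are n10 (list 1 only), n01 (list 2
only) and n11 (both). The model is Poisson log-linear,

    log E[n_xy,s] = γ_s + β₁·x + β₂·y + α·xy ,

with stratum intercepts γ_s, list effects β₁, β₂ shared across strata, and
the list dependence α — the log cross-ratio between list memberships —
entered as a *fixed offset*, not estimated (it is unidentifiable from two
lists). The missing cell per stratum is n̂00,s = exp(γ_s) and

    N̂ = n_observed + Σ_s exp(γ_s).

With a single stratum and α = 0 the fit equals the Lincoln–Petersen closed
form n̂00 = n10·n01/n11 exactly (the model is saturated), and in general
n̂00(α) = n̂00(0)·e^α per stratum; both identities are enforced to 1e-6 in
the test suite, the first against the closed form as an independent oracle.

**Confidence intervals.** A Wald interval for log Σ_s exp(γ_s) is computed
by the delta method over the GLM coefficient covariance and exponentiated;
the interval for N̂ adds the observed count to both bounds. For a single
stratum this reduces to n̂00·exp(±1.96·√(1/n10 + 1/n01 + 1/n11)). On the
2015 aggregate cells (599, 36, 487) this gives 44.28 → (31.3, 62.7) and a
total of 1,166 (1,153, 1,185); the upper bounds round one unit above the
published (31, 62) / (1,153, 1,184), consistent with the published fit
being stratified by quarter (those quarterly cells are not reproduced in
the available text, so the aggregate fit is the canonical in-repo fixture).

**Coverage proportions.** Documented counts are divided by the
integer-rounded point estimate and rounded interval bounds (the scale on
which totals are reported): 523/1166 = 44.9% and 1086/1166 = 93.1%. Using
the unrounded estimate would give 44.8%; the rounded convention is what
reproduces the published percentages and is applied uniformly.

**Redistribution of unmatched cases.** Media-list cases that fail to link
to a mortality record are assumed classified at the same rate as linked
cases: round-half-up of n_unmatched × (matched classified / matched total)
is added to the both-lists cell (95 × 444/991 → 43) and the remainder to
the media-only cell (52). Across quarters the both-cell share is allocated
by largest remainders over quarterly unmatched counts, with quarters taken
from injury dates (unlinked cases have no death date).

**Dependence sensitivity.** Positive list dependence biases the
independence estimator downward, so a sensitivity scan refits the model
over a grid of α. At the largest pairwise list correlation reported for
comparable two-list homicide systems, α = 0.93, the aggregate cells give
N̂ ≈ 1,234 (the published stratified fit prints 1,233).

## Exclusion filters

Media registries use a broader case definition than the ICD legal
intervention category, so raw cases pass through a fixed rule cascade:
death in the following calendar year → friendly fire → domestic violence →
vehicle-struck without pursuit or intentional transport injury → in-custody
death without a qualifying mechanism (Taser, neglect, chokehold, withheld
essential care) or homicide ruling → included. The cascade order is a
design choice (the criteria themselves carry no precedence); it guarantees
one canonical exclusion reason per record, and inclusion counts are
order-invariant. Narrative free text is never parsed — the flags must
arrive as precomputed boolean columns.

## Deterministic linkage

Candidate pairs require a case-insensitive exact first name, surname
Levenshtein distance ≤ 2 (computed with edlib; the threshold is
configurable and covers single typos and transpositions), and birth year
within ± 1 of (study year − media-reported age). Candidates are resolved on
death date and state: within ± 4 days of the injury date and the same state
is a match; a death more than 4 days *before* the injury is rejected; a
later death date or differing state survives only when the case carries an
external news-confirmation flag. Among surviving candidates the smallest
date distance wins; residual ties are reported unmatched (conservative —
an ambiguous link is worse than a missed one). Match-rate tables use
Clopper–Pearson intervals; Fisher exact tests of rate differences are
enumerated exhaustively for r×2 tables when the margin-constrained table
space is ≤ 5×10⁶ tables (verified exactly against R's `fisher.test`),
otherwise estimated by seeded Monte Carlo over fixed-margin tables
(2×10⁵ draws, add-one estimator).

## Misclassification analysis

A matched death is misclassified when none of its ≤ 20 multiple-cause
ICD-10 codes lies in {Y35.0–Y35.4, Y35.6, Y35.7, Y89.0}. Underlying causes
are grouped by first matching range in a fixed order: legal intervention
(Y35 except Y35.5; Y89.0) → assault (X95–Y09) → undetermined/missing
(Y10–Y34; R99) → suicide (X60–X84) → accident (V01–X59) →
circulatory/respiratory (I00–J99) → mental/behavioural (F00–F99) → other.
Range membership is computed on the normalized 3-character category
(uppercase, decimal dropped) with lexicographic comparison, plus the
optional 4th character where a specific code is singled out. Stratified
tables report Clopper–Pearson intervals and chi-squared tests of
independence without continuity correction; a "missing" covariate stratum
is displayed but excluded from the test.

### Nested random-intercept logistic model

Correlates of misclassification are modelled as

    logit P(misclassified) = x'β + σ_c z_county + σ_s z_state ,
    z ~ N(0, 1) i.i.d., counties nested in states,

maximizing the Laplace-approximate marginal likelihood over (β, σ_c, σ_s).
Random effects enter on the standardized scale, which keeps the objective
smooth at σ = 0; at that boundary the approximation *equals* the ordinary
logistic likelihood, so the degenerate limit collapses exactly onto a
plain logistic fit. Implementation notes:

- the inner mode-finding Newton solver exploits the nested structure: the
  negative Hessian is block-arrow per state (diagonal over counties plus a
  state border row), so steps and the Laplace log-determinant are O(n) via
  Schur complements;
- near the mode, full Newton steps are taken on the gradient-norm
  criterion alone — objective comparisons there are at floating-point
  resolution and would stall a line search;
- the outer optimizer is L-BFGS-B with variance bounds at zero; fitted
  standard deviations below 0.15 are refit pinned at zero and the boundary
  solution is preferred unless the log-likelihood worsens by more than
  1e-3 (the Laplace objective's own accuracy in that regime);
- fixed-effect covariance comes from the numerically differentiated
  observed information, dropping boundary variance rows;
- reference levels: ages 18–44, men, white, firearm, medical examiner,
  medium metro, highest income quintile.

The fit was verified against lme4's `glmer` (Laplace, `(1|state/county)`)
on a frozen 6,000-record dataset: coefficients and variance components
agree to ~3 decimals, the log-likelihood to 3×10⁻³.

**Marginal predicted probabilities** fix the variable of interest at each
level for every record, keep all other covariates at observed values, set
random intercepts to zero (the population-median county/state — the
between-cluster variability is deliberately excluded from these summaries),
and average the inverse-logit predictions; intervals are delta-method Wald
intervals over the fixed-effect covariance.

## Synthetic two-list registry generator

The generator emulates the study's data structure so every stage is
testable without restricted mortality data. Study-condition defaults:
true total 1,166 deaths in calendar year 2015; media capture probability
0.931; list dependence α = 0 (configurable); covariate mixes at the
observed 2015 marginal frequencies (70.7% ages 18–44, 96% men at 1043/1086,
92.8% firearm, race/ethnicity and county covariate mixes likewise);
misclassification on the conditional logit scale with intercept −0.056
(≈ logit of the firearm-death predicted probability 48.6%), a non-firearm
log-odds of ln 68.24 and income-quintile effects of ln 7.0–ln 10.4 for
quintiles below the highest, and random-intercept variances σ²_county = 7.1,
σ²_state = 2.7. Geography defaults to 50 states × 10 counties — about the
491 counties that recorded such deaths in 2015. The within-year timing of
injuries is uniform (no seasonality is asserted anywhere in the inputs).

Mechanics worth noting:

- **Dependence is induced per incident.** Given the media marginal p₁, the
  per-incident classification probability p₂ = 1 − logit⁻¹(β'x + u + v)
  and the target log cross-ratio α, the joint cell q11 is solved on its
  Fréchet interval (bracketed root find; a vectorized bisection handles
  whole cohorts) and the pair (media, classified) is drawn jointly. This
  makes the generator exactly self-consistent with the estimator's offset
  parameterization, which is what the recovery tests exercise.
- **Every death enters the mortality collection**; only its coding varies.
  Classified records receive a legal-intervention code (underlying, or —
  rarely, rate 0.002 — only among multiple causes, mirroring the
  multiple-cause rescue); misclassified records draw an underlying cause
  from mechanism-specific mixtures patterned on the observed cause
  distributions (firearm → overwhelmingly X95 assault; Taser → a spread
  over assault, undetermined, accident, circulatory and behavioural codes).
- **Identifier noise** applies single-character surname substitutions and
  ± 1 birth-year slips with configured probabilities, and death-date lag
  with P(lag = 0) = 0.8 (most such deaths are immediate) and a geometric
  tail, censored at Dec 31 so annual truth accounting is conserved.
  Quarters are assigned from death dates (vital-statistics counts are
  death-date based). Lags beyond the 4-day matching window set the
  news-confirmation flag on the media record, mirroring how later death
  dates are verified in practice.
- **Names** are assembled from syllables — no real-person data anywhere —
  and by default an ambiguity guard keeps (first name, surname
  neighbourhood, birth-year window) combinations unique so linkage can be
  scored against truth without genuine ambiguity.
- One global seed; all substreams derive from it deterministically.

What the generator does *not* emulate: media coverage heterogeneity by
rurality (beyond an optional per-urbanicity capture override), duplicate
or garbled mortality records, within-county covariate correlation, and
cross-state hospital transfers (injury and death states always agree, so
the state-mismatch linkage path is exercised only by hand-built tests).
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions, not robustness to real-data pathologies.

## Problem sizes used in the checks

Recovery checks run at the sizes the quantities demand: capture-recovery
coverage uses 200 replicates at the study scale (N = 1,166, quarterly
strata); mixed-model recovery uses 5 cohorts of 20,000 deaths over 500
counties in 50 states (medians across seeds compared at ± 25% for the
non-firearm odds ratio and ± 40% for the variance components); the
degenerate σ² = 0 limit uses 100 counties of ~200 deaths each, where
chance between-cluster variation is negligible and the collapse onto
ordinary logistic regression is exact to 10⁻³.

## Known limitations

- The dependence offset α is assumed known in sensitivity analysis; two
  lists cannot identify it.
- Laplace approximation understates variance components when cluster
  sizes are small (a handful of deaths per county); the recovery
  tolerances above reflect that.
- Wald intervals for N̂ are asymptotic; with very sparse single-list cells
  (n01 of a few per stratum) their coverage is approximate.
- The exact quarterly stratification of the published fit is not
  reproducible from the available text; aggregate-cell results may differ
  from the published stratified ones by one unit in the interval bounds.
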