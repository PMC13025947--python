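# Methods

## Distributional model

Analyte values are modelled, per sex, with the Box–Cox Cole–Green (BCCG)
distribution, the three-parameter family behind LMS centile estimation. With
median μ > 0, relative scale σ > 0 and power ν, the transformed score

z = ((y/μ)^ν − 1)/(νσ) for ν ≠ 0, z = log(y/μ)/σ for ν = 0

is standard normal. Two evaluation modes are implemented. The *lms* mode is
the classical Cole–Green form with closed-form centiles
Q_p = μ(1 + νσΦ⁻¹(p))^{1/ν}; it ignores that y > 0 truncates z at
−1/(σν) (ν > 0). The *exact* mode renormalizes the density by
Φ(1/(σ|ν|)), making it a proper distribution on (0, ∞). For CBC analytes
σ|ν| < 0.1, where the truncation mass is < 10⁻²³, so the two modes agree far
beyond double precision; *lms* is the default for all fitting and centile
prediction and *exact* exists mainly as an oracle for tests. The ν = 0
branch is taken whenever |ν| < 10⁻⁸, which keeps every function continuous
in ν. Sampling is inverse-CDF of uniforms, so streams are reproducible from
a seed on any platform.

Scores (∂ℓ/∂μ, ∂ℓ/∂σ, ∂ℓ/∂ν) are analytic, including the truncation-term
corrections in exact mode and the ν → 0 series limit, and are verified
against central finite differences at random parameter points.

## Age-continuous fitting

μ(age) and σ(age) are penalized B-splines: cubic bases on equally spaced
knots (Eilers–Marx convention: 20 inner knots over [18, 80], degree-fold
boundary extension, K = 24 basis functions) with a second-order difference
penalty. Equal spacing rather than quantile knots is deliberate — health-exam
age distributions concentrate heavily around the thirties, and quantile knots
would starve the old-age end. Both parameters use a log link, so positivity
of μ and σ is structural; an identity-μ option exists but the log link
removes a failure mode in sparse old-age resamples at negligible cost
in-range. ν is a scalar.

Fitting is an RS-style backfitting loop:

1. μ-step: Fisher-scoring P-spline update — working response
   η_μ + u/w with u the score on the link scale and w a numeric second
   derivative (central differences, step 10⁻⁴, floored at 10⁻¹⁰, falling
   back to u² where non-positive);
2. σ-step: identical structure;
3. ν-step: safeguarded Newton on the profile likelihood (numeric
   derivatives, step clipped to 0.5, bounds ±10).

Every update is guarded by step-halving on the penalized global deviance
(−2ℓ + λ_μ β_μᵀPβ_μ + λ_σ β_σᵀPβ_σ), so the deviance is non-increasing
across accepted iterations. The loop stops when the relative deviance change
drops below 10⁻⁶ (default; max 50 outer iterations). Initialization: β_μ
from a penalized smooth of log y, σ⁰ = sd(log y) constant, ν⁰ = 1.
Observations are sorted by (age, value) before fitting, which makes the fit
bit-identical under permutation of the input.

### Smoothing selection

The default pins the flexibility of each smooth by effective degrees of
freedom: **edf 3.5 for μ(age), 3.0 for σ(age)**, converted to λ by bisection
on the monotone edf(λ) curve at the working weights. Adult hematology trends
are gentle (the whole median trajectory spans a few percent over 60 years),
and a simulation study on the generator showed that the alternative —
minimizing GCV — leaves edf ≈ 8–12 and inflates variance at the sparse age
edges past 1% relative error, while the oversmoothing bias at edf 3 is below
0.2%. Fixing a small edf is also the classical LMS practice. GCV selection
remains available (`select_lambda`: 61-point log₁₀ grid on [−4, 8] plus
golden-section refinement), with an edf inflation factor γ = 1.4 in the
denominator (n − γ·edf)² — the standard countermeasure to GCV's shallow
minimum, without which pure-noise inputs occasionally get edf ≈ 16. Fixed-λ
overrides are exposed for both parameters. λs are selected once per fit and
frozen across outer iterations (re-selection each iteration is a config
switch); stability across bootstrap resamples matters more than the marginal
likelihood gain.

Ages outside [18, 80] at prediction time are clamped to the boundary:
reference limits beyond the observed range are flat-extended, never
extrapolated.

## Cohort construction

Linkage is deterministic on exact (person id, date); exam dates match lab
specimen receipt dates, and unmatched rows on either side are tallied.
De-duplication keeps the latest record per person (training) or per
person-year (validation); same-date ties keep the larger row ordinal, which
is deterministic under stable input order. Value cleaning strips "<"/">"
qualifiers, parses decimals, and maps anything non-parsable, zero or
negative to missing — a total function. Eligibility requires age 18–80, a
recognizable sex code, complete BMI/SBP/DBP and CBC values, BMI in
[18.5, 24.0) kg/m² (Chinese adult normal-weight criteria, matching the study
setting), SBP < 140 and DBP < 90 mmHg, and an empty history-flag field; the
exclusion tally records the *first* failing criterion in that fixed order,
so counts are reproducible and sum to the number excluded. All cut-offs are
configuration, since "normal BMI" and "normal blood pressure" are criteria
names, not numbers.

Winsorization clips each sex's training values at the empirical 0.5th/99.5th
percentiles, computed with the linear-interpolation (type-7) quantile rule —
the one empirical-quantile convention pinned across the whole package
(winsorization, bootstrap CIs, median/IQR summaries), because replaced-value
counts and CI endpoints depend on it. Winsorization is training-only:
clipping validation values would bias flag rates downward. Note that exact
idempotence of winsorization is impossible under interpolated quantiles (the
0.5th percentile of already-clipped data interpolates slightly above the
original cut); a second pass moves values by less than one order-statistic
gap.

## Bootstrap reference tables

B = 100 iterations (default): each draws n observations with replacement,
refits the centile model, and evaluates the 2.5/25/50/75/97.5 percentile
curves on integer ages 18–80. Per-iteration RNGs derive from
SeedSequence([master_seed, b]), so iterations are independently reproducible
and aggregation is order-independent. Points are the mean over converged
iterations; 90% bands are the 5th/95th bootstrap percentiles. Non-converged
iterations are dropped and counted — retrying would bias toward easy
resamples — and more than 10% failures aborts the run. ν is re-estimated in
every iteration (full refit). Cell-wise ci_low ≤ point ≤ ci_high is *not*
asserted (a mean can exceptionally leave the 5–95 band); percentile
monotonicity of the points at each age is.

## Validation and the z-index

Classification looks limits up at floor(age) clamped to [18, 80] — matching
the integer-age grid of the published-table artifact, so validation is
reproducible from the table alone — and counts boundary-equal values as
within-interval. Percentages are kept as raw fractions internally and
rounded (2 decimals, half-even) at report time. The stability check passes a
stratum iff L% + U% < 10. The z-index Φ⁻¹(F(y; μ(age), σ(age), ν)) gives a
dimensionless, unit-free deviate (0 at the median, ±1.96 at the outer
centiles) for cross-analyte comparison; in lms mode it reduces to the
Box–Cox z itself.

## Synthetic data: what it does and does not emulate

`gen_model_cohort` draws from a declared BCCG trend. The default red-cell
trends interpolate (monotone PCHIP) sex-specific median control points —
female ≈ 4.50 ×10¹²/L at 18, dipping through the thirties, a small rise
around the menopausal transition, then decline; male declining steadily from
≈ 5.19 — with constant σ and ν per sex solved exactly from the age-18
(Q2.5, Q50, Q97.5) anchors (female σ ≈ 0.0626, ν ≈ −0.32; male σ ≈ 0.0580,
ν ≈ −0.63). Ages are sampled from a discrete right-skewed distribution
(shifted lognormal bulk, median 35, IQR 30–44) with a 10% uniform floor so
every adult age keeps a few dozen observations at n = 20 000, as real
check-up populations do. The generator returns the exact quantile function
as ground truth.

`gen_messy_cohort` emits raw exam/lab CSVs with planted pathologies — 
off-day lab dates, blank fields, "<x"/">x" qualifiers (recoverable),
"NA"/junk strings (fatal), out-of-range BMI, hypertension, history flags,
duplicate earlier visits — at most one pathology per person, drawn by
cumulative rates in a fixed order, so the ledger's eligibility labels are
exact and the cleaning pipeline can be tested without tolerance.
`gen_annual_cohorts` produces independent yearly cohorts with an optional
cumulative multiplicative drift on μ to stress the stability check.

What the generator does **not** emulate: analyzer platform changeovers,
within-person correlation across repeat visits, missing-not-at-random
patterns, subclinical disease contaminating the "healthy" pool, or secular
trends. Passing tests therefore demonstrate that the estimator recovers a
known BCCG truth and that the pipeline's logic is exact — not that real
hematology data satisfy the BCCG-with-smooth-trends assumption.

## Problem sizes in tests and studies

The simulation studies use n = 20 000 per sex for training and calibration
(comparable to the per-sex size of a large single-center training cohort),
50 000 fresh draws for tail calibration, five 20 000-person annual cohorts
for stability, and 60 replicates × B = 60 at n = 500 for the coverage study
— the replicate count keeps the binomial noise on coverage near ±4
percentage points, so the acceptance band for nominal 90% coverage is wide
(75–100%).

## Known limitations

* Constant ν per sex: strongly age-varying skewness would be absorbed into
  σ(age) instead.
* The working-weight step uses numeric differentiation; with extreme
  parameters the quasi-Fisher fallback can slow convergence.
* Old-age estimates ride on few observations; the bootstrap bands widen
  there, and the flat extension beyond age 80 is a convention, not an
  estimate.
* KS normality is reported with sample-estimated moments (conservative
  p-values, logged as such) because that is the conventional reporting
  practice it mirrors; a Lilliefors correction is deliberately not
  substituted.
* The bootstrap treats records as independent — true here by construction
  (one record per person), but an assumption for other data sources.
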