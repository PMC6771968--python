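# Methods

This note documents the statistical content of `necsuff`: the measures,
the estimators, the population calculators, the bootstrap, the
synthetic-data generators, and the numerical and design choices made
where more than one reasonable option existed.

## Measures for dichotomous outcomes

For an event D with unconditional probability p = P(D) ∈ (0, 1) and a
prognostic factor X with conditional probabilities p(x) = P(D | X = x),
the *protective* range of X is {x : p(x) < p} and the *harmful* range
{x : p(x) > p}.  Values with p(x) = p are non-informative and excluded
from both.  The degree of necessity and of sufficiency are

* DN1 = sqrt(E[((p − p(X))/p)² | protective]),
  DN2 = E[(p − p(X))/p | protective];
* DS1 = sqrt(E[((p(X) − p)/(1 − p))² | harmful]),
  DS2 = E[(p(X) − p)/(1 − p) | harmful].

The kernels are normalised departures towards the extremes: DN = 1 iff
p(x) = 0 on the whole protective range (the event cannot occur without
the cause), DS = 1 iff p(x) = 1 on the whole harmful range (the event
is unavoidable with it).  Because the kernels live in [0, 1], Jensen's
inequality pins the variants to DN1² ≤ DN2 ≤ DN1 (same for DS) — a
property-tested invariant.

Estimation replaces the conditional expectations by sample means over
the subjects with p̂ᵢ below/above the baseline p̄ (`estimate_from_probs`).
Ties p̂ᵢ = p̄ are excluded by strict comparison; a configurable absolute
tolerance widens the tie zone if a caller needs it (default 0, i.e.
exact ties only).  An empty informative set yields the value 0 — the
measure of "no informative observations".

**Baseline choice.**  When outcomes are supplied, p̄ defaults to the
outcome mean (the model-free choice); otherwise to the mean of the
predictions.  The two coincide exactly for calibrated models, which is
also the assumption under which the explained-variation algebra below
is exact.

**Explained variation.**  EV is Schemper's predictive-inaccuracy
measure, EV = 1 − E[p(X)(1 − p(X))]/(p(1 − p)).  Under calibration
(E[p(X)] = p) it equals the squared-deviation form
E[(p(X) − p)²]/(p(1 − p)), and splits over the two ranges into

    EV = (1 − α)·odds(D)·DN1² + α·odds(¬D)·DS1²,  α = P(harmful).

`estimate_from_probs` computes both forms (plug-in of the inaccuracy
form is the default; a flag selects the squared-deviation form) and
reports both raw values.  For miscalibrated inputs the selected form
can leave [0, 1]; the headline value is then clipped with a warning
while the raw fields keep the evidence.  EV ≥ DN2·DS2 holds under
calibration and is asserted over randomised inputs.

**The 2x2 case.**  For a single dichotomous factor with counts a, b
(non-events at X=0, X=1) and c, d (events), the level with the lower
event rate is protective; for ad − bc > 0 that is X=0 and

    DN = (ad − bc)/((a+c)(c+d)),  DS = (ad − bc)/((a+b)(b+d)),

with mirrored formulas when X=1 is protective.  Both variants coincide,
DN equals the attributable risk, DS the reverse attributable risk, and
EV = DN·DS = (ad − bc)²/∏margins exactly (the binary R² / φ²).
Swapping the exposure coding leaves all three unchanged.  Estimates
assume representative (cross-sectional/cohort) sampling — not
case-control data — and no truncation is applied to point estimates
outside the bootstrap.

**Partial measures** are differences of nested-model estimates on the
same subjects.  They can be negative in samples; they are returned
as-is with a warning, since no truncation convention exists for them.

## Measures for survival outcomes

At a fixed time t, comparing conditional and unconditional cumulative
incidences F(t|x) and F(t) is exactly the dichotomous problem, giving
per-time kernels DN_t, DS_t.  The overall measures average these over
the event-time distribution on [0, τ]:

    DN1(τ) = (∫₀^τ f)⁻¹ ∫₀^τ sqrt(E[((F(t)−F(t|X))/F(t))² | <]) f(t) dt

and analogously for DS1 and the mean-kernel variants.  In a sample with
distinct event times t_(j) (d_j events each), the estimate is the
weighted average of the per-time estimates with weights d_j/Ĝ(t_(j)⁻),
where Ĝ is the Kaplan-Meier estimate of the censoring ("potential
follow-up") distribution — the product-limit estimator with the event
indicator reversed.  The reciprocal weights undo the thinning of late
observed events by earlier censoring; the simulation suite confirms the
estimates are unaffected by administrative censoring up to 90%.

Numerical conventions for the weights: at tied times, events are
removed from the risk set before censorings, and Ĝ is evaluated as its
left limit at each event time.  Together these guarantee weights that
are finite, ≥ 1, and never condition on censorings tied to the event
time itself.  Beyond the last censoring, Ĝ holds its final value.

**Empty informative sets.**  The definitions are conditional
expectations, so an event time at which no subject lies on one side
carries no information about that side's measure.  Such times are
dropped from both numerator and denominator of the affected measure
(DN and DS renormalised separately).  The alternative — counting them
as zeros — systematically dilutes the average towards 0 and is
available via `drop_empty=False`.  This situation is not addressed by
the defining formulas themselves; the renormalising choice mirrors
their conditional-expectation reading.

**τ.**  Defaults to the largest event time.  No extrapolation beyond
the observed follow-up is attempted: DN(τ) and DS(τ) are genuinely
functions of the horizon, and making them τ-free would implicitly
extrapolate the fitted model beyond the data.

**Conditional curves.**  The estimators are model-agnostic: any matrix
of F̂(t_(j)|xᵢ) is accepted (`curves_from_matrix`).  Two builders are
provided — group-wise Kaplan-Meier for a single categorical factor, and
a proportional-hazards adapter that delegates to lifelines' Cox fit
(Breslow-type baseline) and evaluates each subject's predicted survival
at every event time.  Identical covariate profiles may share a curve
row (`subject_profiles`), keeping memory proportional to distinct
profiles; this is what makes 100 000-subject two-group validation runs
cheap.

**Explained variation (Schemper-Henderson).**  At each event time t a
subject contributes an absolute predictive inaccuracy: 1 − Ŝ(t) if
still under observation beyond t, Ŝ(t) if known dead by t, and for a
subject censored at c ≤ t the expectation over their unknown status,
(Ŝ(t)/Ŝ(c))(1 − Ŝ(t)) + (1 − Ŝ(t)/Ŝ(c))Ŝ(t).  Averaging over subjects
gives M̂(t) for the unconditional curve and M̂x(t) with each subject's
conditional curve substituted throughout, and

    EV = 1 − Σ_j Ĝ(t_(j)⁻)⁻¹ d_j M̂x(t_(j)) / Σ_j Ĝ(t_(j)⁻)⁻¹ d_j M̂(t_(j)).

A negative value (conditional curves predicting worse than the
marginal) is clipped at 0 with a warning.  The implementation uses
per-group prefix sums, O((n + m) log n) per curve row, and is verified
against a literal per-subject double loop in the tests.  Whether Ĝ is
taken at t or t⁻ here changes results at O(1/n); the left limit is used
for consistency with the DN/DS weights.

All survival estimates depend on times only through ranks, so any
strictly increasing time transformation leaves every output
bit-identical — asserted exactly in the tests.

## Population calculators

Three scenario families, matching the generators:

* **2x2** (P(D), α, OR): the joint distribution with the given margins
  and odds ratio is the admissible root of a quadratic in the
  harmful-and-diseased cell (stable two-root form; root selected in
  [0, min(P(D), π)]).  α is the probability of the harmful level, which
  is X=1 for OR > 1 and X=0 for OR < 1; reciprocal odds ratios are
  handled by solving for OR⁻¹ and swapping the exposure coding, making
  OR ↔ OR⁻¹ invariance exact.  OR ∈ {0, ∞} are structural-zero tables,
  not numerical limits.
* **Logistic-normal** (β₁ = log OR per SD, target P(D)): the intercept
  β₀ is solved by Brent root-finding (tolerance 1e-10) on the marginal
  probability integral; the threshold x\* where p(x\*) = P(D) follows
  from the logit identity; kernels are integrated against the standard
  normal density by adaptive quadrature (absolute/relative tolerance
  1e-8, integration range ±14 SD).  β₁ = 0 is degenerate: all measures
  0, flagged.
* **Two-group exponential survival** (HR, α, τ, censoring): the harmful
  level (probability α) has hazard 1, the protective level hazard 1/HR;
  reciprocal hazard ratios are re-oriented on construction.  This
  orientation is what reproduces the censoring percentages of the
  reference grids; the opposite one does not.  Time integrals use
  adaptive quadrature, with the sufficiency kernel rewritten as a
  survival ratio 1 − S_h(t)/S(t) (saturating at 1 once the ratio
  underflows) so the far tail is numerically stable on infinite
  horizons.  Type I and administrative censoring share identical
  population measures at a given τ; they differ only in the reported
  censoring fraction — P(T > τ) for type I, E[min(T, τ)]/τ (uniform
  staggered entry) for administrative.

## Bootstrap confidence intervals

Replicates resample whole observation rows and re-run the model fit, so
interval width reflects genuine estimation variability.  The
*direction-consistency rule* prevents the protective/harmful partition
from silently flipping inside a replicate: using the partition frozen
from the original sample (ties belong to neither side), a replicate's
DN and DS are set to 0 whenever the mean replicate prediction over the
original harmful range falls below the mean over the protective range;
EV is zeroed exactly when both are.  For survival data the analogous
rule compares censoring-weighted average conditional incidences over
the original harmful vs protective subject sets.

Methods: percentile and BCa (default, B = 1000).  BCa's bias correction
z0 comes from the share of replicates below the point estimate with a
mid-p adjustment for ties, (#{θ\* < θ̂} + #{θ\* = θ̂}/2)/B — under null
data the truncation rule piles a point mass exactly at a point estimate
of ~0, where the strict-inequality convention would degenerate to
z0 = −∞.  The acceleration constant uses the standard jackknife
skewness formula (0 when the jackknife variance vanishes).  Bounds are
clipped to [0, 1].  Replicates whose fit fails are redrawn and counted;
more than 5% failures aborts the run.  Identical seeds give identical
intervals.

## Synthetic data and the simulation harness

The generators implement the scenario families verbatim: standard
normal X with a logistic link (intercept solved for the target marginal
rate), multinomial 2x2 draws from the scenario cells, and two-group
exponential times with no censoring, fixed-horizon (type I) censoring,
or uniform-entry (administrative) censoring.  Replicate seeds derive
from the base seed by `SeedSequence.spawn`, so each replicate is
reproducible from (seed, index) alone.

`simulation_study` runs generate → fit → estimate (→ bootstrap) per
replicate and reports bias quartiles and, when intervals are requested,
empirical coverage and mean width.  Default n_sim = 250; the coverage
validation runs 200 datasets × 200 BCa replicates, a deliberate
scale-down of the reference design's 1000 × 1000 chosen to keep the
full validation suite at desk scale (the Monte-Carlo standard error of
a ~95% coverage estimate at 200 datasets is ≈ 1.5 percentage points,
comfortably inside the ±3-point band used for the check).

What the generators deliberately do *not* emulate: covariate
measurement error, model misspecification (the fitted logistic/Cox
models are correctly specified by construction), informative censoring,
competing risks, left truncation, or time-dependent covariates.
Passing validation therefore shows the estimators recover the truth
when their assumptions hold — not that they are robust to violations
of them.

## Known limitations

* No competing risks, left truncation or time-dependent covariates;
  status coding is fixed to 1 = event.
* No case-control adjustment: the baseline event rate must be
  estimable from the sample.
* The population survival calculator covers two-point and standard
  normal factor distributions; other distributions are reachable by
  large-n simulation through the estimators.
* Per-subject Cox conditional curves hold an n × m matrix in memory;
  for very large samples with a categorical factor, use the stratified
  builder, which stores one row per level.
* Point estimates of DN/DS on null data are biased upwards (the
  measures are bounded below by 0); the bias grows with heavy
  censoring.  The simulation harness quantifies this; the bootstrap
  intervals remain calibrated.
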