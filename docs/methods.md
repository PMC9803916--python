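# Methods

## Data model and conventions

The unit of time is decimal weeks from the first radiotherapy fraction
(T₀). Visit weeks are schedule labels, not calendar dates: the default
schedule places weekly on-treatment visits at weeks 1–5 and 5.6 (the last
of 28 fractions) and post-treatment visits at 6.6 and 8.6 — the "end of
treatment" and "end of acute follow-up" reporting landmarks are the last
week of each phase. Grades are opaque ordinal labels 0–4; grade 4 is kept
in the domain even though the generator never produces it by default, so
the zero-G4 property of a cohort is testable rather than structural.
Missing visits are allowed (sparse trajectories) and nothing is imputed
between visits. Patient identifiers are opaque strings.

Two analysis populations are derived, never stored: the toxicity set
(patients with ≥ 1 grade observation) and the oncologic set (additionally
excluding patients whose metastatic disease was detected at or before the
start of radiotherapy — such patients contribute toxicity data only).

## Toxicity index

With grades sorted non-increasingly, TI = Σᵢ g(i) / Πⱼ<ᵢ (1 + g(j)).
Zeros contribute nothing and leave the running product unchanged, so
trajectory length does not dilute scores. The series is the unique simple
form with all four advertised properties (integer part = maximum grade;
strict increase under any added positive grade; same-grade repeats
bounded by the single next-higher event; ranking preservation under
element-wise dominance), and the test suite proves all four by exhaustive
enumeration over grade multisets of length ≤ 5 (and length ≤ 6 for the
integer-part property). Post-treatment grades are included by default —
most grade-3 events arise after the last fraction and the index is meant
to cover the whole course — with an `include_post_treatment=False` switch
for acute-window-only scoring. Scores are exact rationals evaluated in
floating point; comparisons use a 1e-12 tolerance (`TI_TOLERANCE`).

## Onset incidence and exact tests

Onset of grade ≥ g is interval-censored between weekly visits; the visit
week at which the threshold is first met is used as the event time (right
endpoint). Patients never reaching the threshold are censored at their
last visit. Incidence is the Kaplan-Meier complement, so with complete
follow-up it reduces to the crude landmark proportion. No competing-risks
estimator is used (no death or metastasis preceded onset in the acute
window this emulates), and no multiplicity correction is applied anywhere
— single unadjusted p-values mirror the trial's reporting. The two-sided
Fisher exact p sums hypergeometric probabilities not exceeding the
observed table's (point-probability ordering, as in R's `fisher.test`);
this convention reproduces all three published subgroup p-values
(0.0108, 0.0198, 0.6989 → printed 0.01 / 0.02 / 0.70).

## Probabilistic index model

Pseudo-observations are all ordered pairs of distinct patients with
response r₍ᵢⱼ₎ = I(Yᵢ < Yⱼ) + ½ I(Yᵢ = Yⱼ) and design Z₍ᵢⱼ₎ = Xⱼ − Xᵢ.
The ½-tie convention is mandatory: toxicity-index ties are inherent to
discrete grades. The link is logit (the conventional default of PIM
software; probit is not implemented). The estimating equation
Σ Z (r − expit(Zᵀβ)) = 0 is solved by Newton iteration with step-halving
(up to 20 halvings, never accepting a step that increases the score norm),
convergence at max|U| < 1e-8 and step norm < 1e-10, at most 100
iterations. Fitted linear predictors beyond ±15 are treated as complete
separation and raise an explicit error suggesting a boundary PI report —
at that magnitude the estimating function can fall below tolerance while
β diverges, so a "converged" result there would be spurious.

The variance is the sandwich A⁻¹BA⁻¹: A is the estimating-equation
Jacobian; B sums score cross-products over every two pairs sharing a
patient, accumulated in O(pairs) by per-patient score totals Sₖ
(Σₖ SₖSₖᵀ counts combinations once per shared patient, so one copy of the
self- and reversed-pair terms is subtracted). For the unadjusted
two-group model the root of the estimating equation is exactly the
empirical placement probability mapped through the link — the brute-force
pair-count oracle used in the tests — and the Wald interval, formed on
the linear-predictor scale and mapped through the inverse link (hence
always inside (0, 1)), covers a known PI in ~95% of simulated 25 + 25
cohorts.

The trial-level model regresses the toxicity index on arm indicators
(alternate, daily; no-bolus reference) over the whole toxicity
population in one model — whether the published analysis ran per-stratum
models is unstated, and a single model keeps both contrasts against the
common reference — optionally adjusted for age (continuous), obesity
(BMI ≥ 30 indicator), diabetes, smoking history, and CT planning.
Reported PI contrasts are indicator differences evaluated at zero
covariate difference. The trial's own PI of 88.4% cannot be reproduced
without patient-level data; on the printed-counts fixture the unadjusted
daily-vs-no-bolus PI is 0.92 with CI excluding 0.5, which is the
qualitative anchor the pipeline is expected to show.

## Quasi-Poisson relative risks

Endpoints are per-patient binary indicators built from first-exceedance
weeks: grade ≥ 2 by the end-of-treatment week, grade ≥ 3 by the
end-of-acute-follow-up week, with no person-time offset. This
construction reproduces the published grade-3 row exactly (daily 7/10 vs
pooled 1/41 → RR 28.70, Wald CI 4.03–204.33, Pearson χ² = 43.0 on 49 df,
dispersion 0.878), which validates the endpoint/landmark reading of the
table. Estimation is statsmodels GLM (Poisson, log link) with covariance
scaled by Pearson χ²/(n − p); intervals use exp(β ± 1.96·se) and are
symmetric only on the log scale. Groups with zero events put the log-mean
at −∞; rather than emitting a spuriously huge finite RR, the fit raises a
boundary error naming the term (no continuity correction is applied —
the trial avoided the situation by pooling arms). The published
unadjusted grade-2 RRs are not reproducible from any proportion-based
reconstruction of the printed grade-2 counts (the counts and the text
percentages disagree in the source); they are deliberately not targets,
while the grade-2 *counts-based* fit is still produced for completeness.

## Survival

Local control is Kaplan-Meier from T₀ with Greenwood variance and
events-before-censorings tie handling; landmark estimates read the step
function at exactly 5.0 years (the value just after the last event at or
before 5.0). Log-rank tests use the standard pooled risk-table statistic
with k − 1 degrees of freedom; a comparison with no events anywhere
returns statistic 0, p = 1, flagged degenerate. The published 5-year
estimates (95.8%, 91.7%) depend on the trial's unknown censoring pattern
and are conventions for the fixture, not reproduction targets; generic
curves and tests are also usable for metastasis-free interval and overall
survival, whose published comparisons are not in the available text.

## Synthetic-data generator

The generator emulates design, not biology. Grade paths are monotone
non-decreasing through the acute window — no healing is modeled before
week 8.6, which is immaterial because every downstream statistic uses
only first-exceedance times and maxima. At each visit the grade steps +1
with a probability specific to randomization subgroup, current grade, and
phase; post-treatment visits allow only the 2→3 step (late grade-3 onset,
as dominated the trial) — so the emergent split of grade-3 onsets between
phases is not separately tuned. Upon an on-treatment grade-3 event in a
bolus arm the bolus stops and subsequent steps use the no-bolus column
scaled by a configurable multiplier (irrelevant under defaults, where
grade 3 is terminal: no 3→4 step is modeled because no grade-4 events
occurred).

Defaults are the study conditions: 32 standard-risk and 19 high-risk
patients; obesity probability 0.353; age ~ N(50, 10) truncated to
[25, 85]; diabetes 0.137; ever-smoking 0.314; CT planning 0.588 (baseline
marginals of the trial); metastasis-at-or-before-RT probability 0 /
0.158 per stratum (3 of 19 high-risk); 5-year local control 0.958 / 0.917
with exponential failure times and administrative censoring uniform
within ±1 year of the 6.2-year median follow-up (the real accrual and
censoring calendar is unknown; this is a declared convention). Covariates
carry no toxicity effect by default — they exist so confounding
experiments can switch effects on.

Step probabilities are not magic numbers: the grade-0→1 probability is
fixed at 0.85 everywhere (probability ~1e-5 of never reaching grade 1 in
six visits, matching "all patients develop grade 1" while preserving
onset-week variation), and the 1→2 and 2→3 probabilities are found by
bisection against the printed subgroup incidences (G2 at end of RT:
33.3 / 23.5 / 44.5 / 100%, capped at 99.5% since a probability-1 target
is unattainable; G3 by end of acute follow-up: 0 / 0 / 11.1 / 70%) using
an exact forward computation of the chain — `radstox calibrate` prints
them. Calibration is per (stratum × arm) cell because the alternate arm
has different printed incidences in the two strata. Randomization uses
permuted blocks (default size 2) within risk × BMI cells, each cell
owning an independent seed stream so enrolling more patients into one
cell never reshuffles another; likewise each patient's covariates,
trajectory, and outcomes come from a stream keyed by (master seed,
patient index).

The deterministic fixture cohort encodes the printed counts directly:
arm sizes 15/17/9/10; grade-2 landmark counts 5/4/4/10; grade-3 counts
0/0/1/7 with five of the eight onsets at post-treatment visits and the
three on-treatment events (one alternate, two daily, all high-risk) in
the last treatment week with bolus discontinued there; maximum-grade
distribution 28/15/8; covariate counts per arm from the baseline table,
interleaved deterministically; one local failure per arm and three
metastatic flags (one alternate, two daily) giving the 51/48 analysis
populations. Every patient is observed at all eight visits so
Kaplan-Meier landmarks equal crude proportions — the trial gave the two
extra post-RT visits only to grade-3 patients, but a censoring-free
fixture is what makes the printed proportions recoverable. Grade
trajectories were chosen so daily-arm and no-bolus scores overlap
(including one exact tie), keeping the fixture PIM away from separation.

What passing tests on these cohorts do **not** show: robustness to
within-window grade regression, informative censoring, visit
non-adherence, or covariate-driven toxicity — none of which the generator
produces. Parameter-recovery checks therefore also use two direct
generators with closed-form truth: normal-shift score pairs with
placement probability Φ(δ/√2) = PI, and binary two-group outcomes with a
configured risk ratio.

## Problem sizes and numerical choices

Coverage and recovery studies run at 500 replicates of 25 + 25 (PIM
coverage band 90–98%), 200 replicates of 200/arm (PI recovery within
±0.05, RR coverage 90–98%), and calibration checks at ~500 simulated
patients per arm within ±4 percentage points — sizes at which Monte-Carlo
error is comfortably inside each band while the whole suite runs in well
under a minute of simulation time. All Wald intervals use z = 1.96. The
Fisher oracle enumerates the full hypergeometric support for margins
≤ 30. Reports are plain delimited text plus a key-value summary with
provenance (seed, config digest, version); identical inputs and seed
yield byte-identical files.
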