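# Methods

## Scope and perspective

The package models the cost difference between two rotational IMRT
techniques — VMAT and helical tomotherapy (HT) — for high-risk prostate
cancer with pelvic nodal irradiation, from the hospital perspective, in
euros of a single currency year and without discounting (the costing
horizon is under three months). Only resources that plausibly differ
between the techniques are costed: the four planning phases (image
registration and contouring, inverse planning, patient-specific QC,
pre-treatment setup verification "D0") and treatment delivery, plus
machine QC and internal maintenance. CT acquisition, bunker construction,
record-and-verify systems, patient-QA software, androgen deprivation
therapy and the treatment of acute toxicity are out of scope by design.

## Costing model

**Labor.** Every event in the resource-use log carries personnel minutes
for one role. An event costs `minutes/60 × hourly wage`, where the hourly
wage is the annual full gross wage (payroll taxes included) divided by
workable yearly hours (default 1,600 h). Simultaneous presence of several
roles is costed additively, one event per role-minute block, because the
chronometer-style logs record all personnel time spent.

**Equipment.** Machines are valued by straight-line, undiscounted
replacement plus upkeep: hourly rate = `(purchase price / lifespan +
annual external maintenance + annual QC/IM labor) / annual operating
hours`. Lifespans are 12 years for accelerators and 5 years for the
treatment planning system (TPS). The HT accelerator price includes its
integrated TPS, so HT patients carry zero TPS components; the VMAT TPS is
amortized over its own operating-hours parameter (default: the same
annual hours as the accelerator — configurable).

**QC / internal maintenance.** The annual dedicated hours of the medical
physicist and biomedical technician are valued at their hourly wages and
summed. This annual amount is folded into the accelerator's annual cost
*before* the hourly rate is formed — the allocation of this annual labor
to individual patients is not otherwise defined, and routing it through
machine-occupancy time treats it exactly like external maintenance, which
it operationally resembles. This is a documented convention, not the only
defensible one.

**Accounting identities.** For every patient, planning cost is the sum of
its seven planning components, session cost the sum of its two session
components, and total = planning + session, exactly (to 1e-9 EUR).
All arithmetic is done at full precision; rounding to centimes happens
only at the printing stage, which is why sums of independently rounded
table cells can disagree with rounded totals by a cent or two.

## Synthetic cohort generator

The generator's defaults are the study conditions; they are not tuning
knobs.

**Arms and assignment.** 106 VMAT and 49 HT patients. Baseline covariates
(age ~ N(68.6, 7.6²); ECOG 1–2 with probability 0.155; cT1..cT4 with
probabilities 0.148/0.290/0.530/0.032; cN1 with probability 0.135; PSA
log-normal, capped at 100 ng/ml — the cap value is a package choice, the
source table only says values were capped) feed a logistic
treatment-assignment model whose coefficients produce the observed
imbalance pattern (notably cN1 prevalence ≈ 9% in VMAT vs ≈ 22% in HT).
Assignment is drawn Bernoulli over an inflated candidate pool and each arm
is then trimmed uniformly at random to its exact target size. Uniform
within-arm thinning preserves each arm's covariate law, so a logistic
propensity model refit on the realized cohort remains correctly specified
up to an intercept shift (the classical retrospective-sampling result);
slope recovery and post-weighting balance are asserted in the tests at
n = 20,000.

**Plans.** Each patient receives a sequential (40-fraction) plan with
probability 0.25, otherwise a simultaneous-integrated-boost (SIB,
34-fraction) plan. The single plan-mix probability is a package choice:
the source reports overall and per-plan cost summaries whose implied
sequential shares differ slightly by arm, but the generator keeps one
cohort-level mix.

**Session times.** Machine-occupancy minutes per session are log-normal
around stratum medians encoding the learning curve — strata {1}, {2–3},
{≥4} with medians 20/15/13 min (VMAT) and 18/18/17 min (HT) — multiplied
by a per-patient log-normal factor (σ = 0.18) that captures
between-patient heterogeneity; the within-stratum noise is σ = 0.15.
Medians are preserved under both multiplicative noises. Session personnel
minutes are an arm-specific multiple of machine minutes (roughly two
radiation therapists, back-solved exactly in calibration). Setting both σ
to zero degenerates every draw to the stratum median.

**Planning times.** Personnel minutes per planning phase are
zero-truncated normal. The *pre-truncation* location is solved
numerically so the *post-truncation* mean hits the calibration target
exactly (a naive location-equals-mean parameterization would inflate
means by up to ~11% at the larger coefficients of variation, which are
capped at 0.6).

**Toxicity.** For each endpoint (GI, GU, sexual) × window (acute ≤ 3
months; late 6–24 months) a proportional-odds model with three ordered
cutpoints generates a collapsed grade 0/1/2/3–4; a positive treatment
log-odds shifts VMAT toward worse grades. Cutpoints are calibrated to the
HT (reference-arm) grade margins of the study's toxicity tables; default
shifts are 0.7 (acute GI), 0.6 (acute GU), 0.3 (acute sexual) and 0 for
all late endpoints — acute toxicity favors HT, late toxicity is null.
Onset months are uniform in (0, 3] (acute) and [6, 24] (late); only the
window bounds are specified by the design, not the within-window shape.
Toxicity follow-up is available with probability 98/106 in VMAT and 1 in
HT, mirroring the study's attrition.

**Determinism.** One RNG stream per cohort, consumed in a fixed substream
order (covariates/assignment → plans → follow-up → resource use →
toxicity). Identical config + seed reproduce the output files
byte-for-byte.

**Calibration of the defaults.** Catalog prices, wages and maintenance
contracts are not public, so the default unit costs are placeholders:
plausible French anchors are fixed (wages; accelerator prices 2.6 M€ VMAT
/ 3.6 M€ HT including TPS; TPS 0.3 M€; annual operating hours 2,513 /
2,520; QC/IM dedicated hours 194.5 / 144 split between physicist and
technician) and the remaining free quantities — maintenance contracts,
planning-phase minutes, session staffing factors, setup-D0 machine
minutes — are back-solved so the *expected* per-component costs equal the
reference component-mean table. Consequently the component *shares* (and
everything derived from shares, such as tornado percentages) are
reproduced by construction, while a finite simulated cohort scatters
around the reference means with the sampling noise of n = 106/49.

**What the generator does not emulate.** Center-level clustering (the
study could not model centers either), Gleason scores, dose/dosimetry,
correlation between planning times and session times, correlation between
toxicity endpoints, and within-patient toxicity trajectories beyond one
worst grade per window. Passing tests therefore demonstrate the
correctness and calibration of the pipeline, not the real-world magnitude
of any clinical effect.

## Propensity weighting and balance

The propensity score is a maximum-likelihood logistic regression of the
HT indicator on the five baseline covariates (age, performance status,
cT contrasts against cT1, cN, capped PSA — Gleason is excluded from the
adjustment set). Stabilized weights multiply the inverse probability of
the received treatment by the marginal arm probability, so the weighted
pseudo-population size stays ≈ n (asserted within 10% at n = 155 and
converging with n). Propensity scores on the 0/1 boundary raise an error
advising covariate review; there is no silent trimming (an optional clip
is deliberately absent by default).

Standardized differences use the convention HT − VMAT (the sign is
arbitrary; it is fixed to make tests deterministic). Continuous: mean
difference over `sqrt((SD²_HT + SD²_VMAT)/2)`; binary: analogous with
`p(1−p)` variances; multilevel (cT): the generalized Mahalanobis form
`sqrt(Tᵀ S⁻¹ T)` over the L−1 level-proportion contrasts with the
averaged covariance matrix. Weighted variants use frequency-weighted
moments with a `Σw − 1` variance denominator, so unit weights reduce
exactly to the unweighted statistics. The exact weighted-variance
convention behind the source's weighted-d column is unstated, so exact
reproduction of that column is not claimed.

## Outcome models

Both effect models adjust for sequential-vs-SIB plan and are run
unweighted and under IPTW. Total cost uses weighted least squares with
HC1 robust standard errors (the weights are estimated, and the source
does not state its variance treatment; the robust choice makes p-values
reproducible within this artifact). Toxicity uses a weighted
proportional-odds (cumulative logit) model, maximized directly with an
analytic score and BFGS after collapsing to unique (grade, design)
patterns — exact for a weighted likelihood — with a sandwich covariance
(`A⁻¹ B A⁻¹`, B accumulating squared weights). It is parameterized so a
positive arm coefficient means higher odds of a worse grade for VMAT;
categories are the four tabulated ordered levels, with absent top
categories dropped consecutively. p-values are two-sided Wald. The
unit-weight case coincides with an ordinary cumulative-logit fit and is
cross-checked against an independent implementation in the tests.
Patients without toxicity follow-up are excluded from the toxicity models
(the weights are not re-estimated on the reduced set; this mirrors the
available-case analysis and is configurable by refitting on the subset).

## Bootstrap

Patients (not events) are resampled with replacement within arm;
stabilized weights travel with their patients and are not re-estimated
per resample — the procedure targets the sampling variability of the
weighted mean cost, not the variability of the weight estimation itself,
and weight re-use is the documented, configurable default. The 95% CI is
rank-based: with B iterations, exactly ceil(2.5% × B) order statistics
are dropped at each tail (25 of 1,000), with a small numerical epsilon so
binary floating-point representation of the tail probability cannot trim
an extra iterate. Fewer than 40 iterations cannot support a 95% interval
and raise an error. Empirical coverage of the true mean is asserted at
93–97% over 500 replicates at the HT arm size.

## One-way sensitivity (tornado)

Each parameter is scaled to ×0.8 and ×1.2 with everything else at
baseline; rows are sorted by descending range. Price, maintenance and
wage parameters act linearly (symmetric bars); annual operating time
enters the machine rate hyperbolically (asymmetric bars: +25% cost at
×0.8 hours, −16.7% at ×1.2). "Accelerator immobilization time" scales the
session and setup-D0 machine minutes jointly, since both are
machine-occupancy components; under the calibrated defaults a −20%
perturbation lowers mean total cost by ≈ 12.1% (VMAT) and ≈ 15.5% (HT) —
exactly 20% of the accelerator-occupancy share of total cost. The
source sentence pairs those two percentages jointly with "a 20% increase
in the annual operating time and a 20% decrease in the accelerator
immobilization time"; component arithmetic shows both printed figures
match the immobilization-time perturbation, and the operating-time
pairing is left as a documented ambiguity. A parameter with zero cost
share (e.g. TPS price in the HT arm) has exactly zero range.

## Numerical choices and degenerate inputs

* Truncated-normal locations and log-normal medians are solved/set so
  configured means/medians are exact; solver tolerance 1e-10.
* The ordinal model's cutpoints are optimized as (c₁, log-increments) to
  enforce monotonicity; fits failing BFGS convergence with a
  non-negligible gradient raise with diagnostics; an all-identical grade
  vector raises immediately.
* Collinear cost-model designs (e.g. plan aliasing arm) are rejected via
  a rank check rather than silently dropped.
* Perfect separation in the propensity model is detected both from the
  optimizer and from boundary fitted probabilities.
* Zero-variance inputs: a degenerate bootstrap collapses to a point CI; a
  zero pooled variance makes d undefined and raises.

## Problem sizes

Statistical property tests run at n = 20,000 (balance, recovery), 500
replicates × 1,000 iterations (coverage), and the study size n = 155
elsewhere; these sizes make the assertions sharp while keeping the whole
suite around ten seconds. The acceptance script simulates one
study-sized cohort (106/49) per run.

## Known limitations

* Unit costs are calibrated placeholders; absolute euro amounts inherit
  their anchors, though shares and identities do not.
* A single cohort-level plan mix cannot reproduce per-arm plan-specific
  cost summaries simultaneously with overall means.
* The pipeline estimates no cost-effectiveness ratio and no quality-of-life
  outcome, models no center effects, and does not re-estimate weights
  within bootstrap resamples.
* Exact reproduction of the source's weighted-d column and toxicity
  p-values is out of reach without patient-level data and is not claimed.
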