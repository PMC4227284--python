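# Methods notes

This note documents the modeling choices behind `wardscore`: what each
stage computes, the assumptions it makes, the defaults and why, and what
the synthetic cohorts can and cannot establish.

## Scoring engine

Each of the nine systems is described declaratively in a JSON fixture:
numeric components carry ordered half-open `[lo, hi)` band tables mapping a
physiologic range to integer points; everything that is not a plain band
lookup (categorical items such as AVPU, boolean comorbidity terms,
composite rules such as APACHE II oxygenation or SOFA cardiovascular) is a
`special_term` resolved by a small hook registry. Band tables must
partition the real line — gaps and overlaps are rejected when the fixture
loads, and a value can therefore never fall outside every band; nothing is
silently clamped. Cut-points are encoded exactly as the source publication
prints them, with the half-open convention resolving boundary membership
the way the source's ≥/≤ notation dictates.

Fixture provenance, in brief:

| score | source | fidelity |
|---|---|---|
| SOFA | Vincent 1996 | transcription (see ward adaptations below) |
| MEWS | Subbe 2001 | transcription |
| ViEWS | Prytherch 2010 | transcription |
| REMS | Olsson 2004 | transcription |
| SAPS II | Le Gall 1993 | transcription (urea → BUN mg/dL) |
| APACHE II | Knaus 1985 | transcription (no ARF doubling) |
| MEDS | Shapiro 2003 | transcription (proxied items, see below) |
| SCS | Kellett 2006 | documented reconstruction |
| PIRO | Howell 2011 (ED variant) | documented reconstruction |

The exact printed SCS and PIRO tables were not available for
transcription; their fixtures are reconstructions that keep the published
item structure and plausible weights, and say so in their provenance
fields. Nothing in the package's verification depends on their exact
weights — the engine-level checks (partition, monotone derangement, range,
oracle equivalence) apply to every fixture equally.

Ward-context adaptations, applied deliberately and recorded per fixture:

* Patients are pre-ICU: `mechanical_ventilation=false`,
  `vasopressors=none`, admission type medical. The SAPS II ventilated-only
  oxygenation term and vasopressor grades of SOFA cardiovascular therefore
  contribute 0; SOFA cardiovascular reduces to the hypotension point
  (MAP < 70 mmHg). A consequence is that an all-normal ward snapshot
  scores 6 on SAPS II (the medical-admission term), which the fixture
  records as its `normal_floor`; all other scores floor at 0.
* MAP is derived as (SBP + 2·DBP)/3 when not recorded directly.
* GCS is not charted on general wards; it is derived from the worst AVPU
  level in the window via the published conversion A→15, V→13, P→8, U→3
  (strictly monotone).
* SCS functional-status items (breathlessness, inability to stand, ECG,
  new stroke) are not collected and score 0 = normal; MEDS items without a
  direct chart equivalent are proxied (terminal illness → metastatic
  cancer; septic shock → severe sepsis with SBP < 90; altered mental
  status → any AVPU impairment).
* APACHE II chronic-health points (5) are granted for nonoperative
  admissions with chronic liver disease, HIV, or metastatic cancer;
  creatinine points are not doubled for acute renal failure, which cannot
  be adjudicated from ward charts. The APACHE II oxygenation term uses
  A-aDO2 at FiO2 ≥ 0.5 and PaO2 below, computed from the blood gas and the
  concurrent FiO2.

## Windows, worst values, imputation

Observations are binned by hours before the index time into half-open
windows `[start, end)` — 0–12, 12–24, 24–48, 48–72 h by default — so a
measurement at exactly index − 12 h belongs to the 12–24 h window. Windows
that predate admission are flagged `in_hospital=false` and excluded from
that window's ROC (scores exist only for time in hospital).

"Worst value" is score-specific: the observation earning the most points
under that score's band table for the component. Ties on points are broken
toward the more deranged value (farther in the component's worse
direction), then toward the observation closest to the index. The
derangement tie-break matters for two-sided tables and plateaus: of two
values scoring equally, the clinically worse one is the worst value.

Missing components are filled by a two-stage cascade: carry from the
nearest window that is *earlier in clock time* (farther from the index)
and actually holds a measured value — never from another carried value —
else assume the documented normal. Carrying only backward-in-time means no
deterioration signal can leak from near-event windows into earlier ones.
The carry rule generalizes a one-step rule to nearest-measured; a strict
`one_step` policy is available in the API. Vitals and labs follow the same
cascade (the uniform choice is logged per component via provenance tags
`measured` / `carried` / `normal_default`). The normal-values fixture is a
single source of truth: the same midpoints parameterize the assume-normal
rule and the synthetic generator's baselines, and each midpoint is chosen
to score 0 points in every system that uses the component (e.g. SBP 115,
DBP 70 so that derived MAP = 85 is normal for REMS/APACHE II while SBP
clears the ViEWS 111 cut).

## Cohort design

Eligibility keeps infection admissions and drops direct ICU admissions and
care-limited patients, with per-rule exclusion counts. A case's index time
is the earliest qualifying event (ICU transfer, consult for ICU transfer,
rapid response, death). Controls are drawn uniformly (seeded) among
never-case survivors admitted the same calendar day with LOS strictly
greater than the case's admission-to-index interval, used without
replacement; the control inherits the case's admission-to-index offset.
Exact-date matching is relaxed day by day up to ±3 only when no same-day
candidate exists (the design states date matching without a tolerance;
small synthetic cohorts would otherwise drop pairs). Excluding future
cases from the control pool is a deliberate deviation from textbook
risk-set sampling, matching the study design this package implements.

## Evaluation

* AUC: Mann–Whitney with ties ½; variance and CIs from DeLong structural
  components; paired comparisons via the DeLong z; unequal-sample
  comparisons via z = (A₁−A₂)/√(v₁+v₂−2ρ√(v₁v₂)) with ρ = 0.5.
  Qualitative tags: AUC ≥ 0.70 "acceptable", ≥ 0.80 "excellent".
* Thresholds and the Δ-rule: scores are integers, so threshold searches
  scan the exact finite grid of observed values; ties prefer the lowest
  threshold (lexicographically smallest pair for the two-threshold rule).
  The Δ-rule grid includes a sentinel above the maximum earliest score so
  the search may ignore the baseline term; the strict `>` on Δ makes the
  maximum observed Δ the ignore-delta sentinel. The per-subject inputs are
  earliest = score in the farthest-from-index in-hospital window,
  latest = the nearest window, peak = max over in-hospital windows,
  Δ = latest − earliest; a patient hospitalized for a single window has
  Δ = 0 by construction and is classified by the baseline term alone.
* Odds ratios: crude OR from the 2×2 cross-product with Woolf CI
  (Haldane–Anscombe 0.5 on zero cells, flagged); adjusted OR from
  unconditional logistic regression on the rule indicator plus age, sex,
  severe sepsis, pneumonia and CHF. Matched-pair (conditional) logistic is
  a recognized alternative for a matched design; unconditional was chosen
  as the default because the matching variable (admission date) is not a
  confounder of physiology, and the adjusted model conditions on the
  measured baseline imbalances directly. Separation raises an explicit
  error recommending a penalized fit rather than returning an unstable
  estimate.
* Trajectories: linear mixed model on windowed scores with fixed effects
  group, window (categorical, earliest window as reference),
  group × window, and the five baseline covariates; random structures
  (patient intercept vs intercept + slope over window time) are compared
  by AIC under ML. Contrasts are within-group consecutive-window
  differences with normal-approximation p-values, plus a joint Wald test
  of the interaction. No multiplicity adjustment is applied; p-values are
  reported raw with α = 0.05.
* Endpoints: the mortality analysis is the same code path with the pair
  set restricted to pairs whose case died in hospital — the endpoint is a
  parameter, not a second implementation.

## Synthetic cohorts

The generator emulates the structure of an ER-admitted ward infection
cohort. Defaults: 656 admissions over ~4 months, deterioration fraction
328/5188 ≈ 6.3%, log-normal time-to-event with median 32 h (σ = 1.7,
matching a long right tail), event mix ICU transfer : rapid response or
consult : death ≈ 142:200:110 with overlap allowed, vitals every 6 h with
97% per-window availability, metabolic panels roughly twice daily at 94%,
blood gases in 30% of patients, and baseline imbalances in age, sex and
comorbidities taken from the case/control prevalences of the design this
package implements (severe sepsis 76%/32%, pneumonia 42%/26%, CHF
38%/30%, …). Panels are twice daily rather than daily because a daily
schedule cannot give >93% availability in a 12 h window.

Physiology is driven by a latent severity scalar: a static per-patient
baseline severity ~ Exp(0.8 SD) shared by cases and controls (ward
infection patients are not healthy — this is what makes a single score
measurement an imperfect classifier), plus, for cases only, a linear ramp
over the final 48 h before the event of 0.5 baseline SD per 12 h,
multiplied by a per-case log-normal factor (σ = 0.5; not every
deterioration is equally fulminant). Each component sees the severity
through its own gamma(2) weight (different patients fail different
organs) and moves toward its deranged side (direction per component from
the normal-values fixture) in units of its baseline SD, truncated to
plausibility bounds. AVPU and supplemental oxygen are deterministic
step functions of the latent severity. Missingness drops whole 12 h
blocks (anchored at the event for cases, at admission for controls) with
probability 1 − availability. All randomness flows from one seeded
generator; identical parameters and seed give identical cohorts.

The paper trail for these choices: the deterioration fraction, event mix,
median time-to-event, availability fractions and comorbidity prevalences
are the stated study conditions; the per-component effect sizes are free
parameters (the study reports none), fixed once at values that give the
qualitative structure such a cohort must have — every score discriminates
in the nearest window and decays toward chance by 48–72 h, the
baseline-heavy MEDS decays slowest, case trajectories rise while
controls stay flat, and the change-aware rule beats single-measurement
models.

What the synthetic cohorts do **not** establish: real-data AUC levels
(the study's patient-level data are not deposited, so absolute AUCs here
are not estimates of the study's), treatment feedback (no interventions),
multi-admission patients, pediatric physiology, or the ICD-9 chart
abstraction pipeline.

## Numerical and degenerate-input conventions

* Band lookup is binary search over lower edges; its oracle (linear scan)
  lives in the tests.
* AUC on a single class, rules on constant indicators, empty groups, and
  index times before admission raise informative errors rather than
  returning defaults.
* Mixed-model fits try BFGS, then Powell, then CG, and report
  non-convergence with diagnostics if all fail; ML (not REML) likelihoods
  are used so AICs are comparable.
* Problem sizes used by the shipped checks — 656-admission cohorts across
  10–20 seeds for simulation properties, 200 replicates for type-I error,
  300–500 for null calibration — were chosen as the smallest sizes at
  which the binomial/asymptotic tolerances in the tests are meaningful.

## Known limitations

* SCS and PIRO weights are reconstructions; absolute totals for those two
  systems should not be compared against published cohorts.
* The AVPU→GCS conversion collapses the 3–15 scale to four values; GCS-
  granular scores (APACHE II neurologic, SAPS II) lose resolution
  accordingly, exactly as they do in ward practice without charted GCS.
* The generator's linear-ramp drift is the simplest mechanism producing
  rising pre-event scores; real deterioration includes non-monotone
  courses (partial responses to treatment) it does not model.
* Control availability blocks are anchored at admission, cases at the
  event; per-window availability is exact for case windows and
  approximate for controls.
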