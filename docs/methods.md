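# Methods

## Model structure

The model compares two strategies for managing blood pressure (BP) in the
first two weeks after a delivery complicated by a hypertensive disorder of
pregnancy: **remote BP management (RBPM)** — home cuff, twice-daily
uploads, staffed clinician response — and **usual care** — discharge
advice plus one outpatient BP visit.  A cohort starts normotensive on the
day of discharge and evolves through fourteen 1-day Markov cycles over six
states:

| state | role |
|---|---|
| `normotensive` | BP < 140/90; baseline state |
| `mild_bp` | SBP 140–159 or DBP 90–109 |
| `severe_bp_unrec` | SBP ≥ 160 or DBP ≥ 110, not yet acknowledged |
| `readmitted` | ED evaluation / readmission for acknowledged severe BP |
| `severe_morbidity` | eclampsia, stroke, or ICU admission |
| `death` | absorbing |

Assumptions baked into the structure:

* **Fresh daily BP draw.**  From the normotensive and mild states the next
  day's BP outcome is drawn from the same five-way distribution
  `(p_norm, p_mild, p_sev, p_morb, p_death)`; the day-1 probabilities are
  held constant across all 14 days (no published time profile exists).
* **Acknowledgment gates readmission.**  Severe-range mass splits on the
  strategy's daily acknowledgment probability: acknowledged severe BP goes
  to `readmitted`, the rest to `severe_bp_unrec`, which carries an extra
  daily preeclampsia death hazard (6e-5) and an escalated morbidity hazard
  (10 × p_morb; the escalation multiplier is a structural constant,
  configurable, chosen because unrecognized severe hypertension is the
  mechanism by which monitoring averts morbidity — no published magnitude
  exists).  Hazards in this state compete in a fixed order (death, then
  morbidity, then acknowledgment), each capped so the row remains
  stochastic under extreme parameter draws.
* **Readmission is a one-day tunnel** returning to `normotensive`:
  readmission treats the hypertension.  This is the simplest structure
  consistent with "severe BP leads to ED evaluation or readmission when
  recognized".
* **No half-cycle correction, no discounting**: with 1-day cycles and a
  14-day costing horizon both are negligible.

### Coupling modes

`direct` (default): the acknowledgment split is scaled by a root-found
factor so cumulative 14-day readmissions equal the per-14-day readmission
inputs (1% RBPM, 5% usual care).  The reference outcome table reproduces
its own readmission inputs exactly, so its analysis treats them as
governing.  `mechanistic`: the published daily acknowledgment
probabilities drive readmission directly (cumulative readmissions then
exceed the per-14-day inputs several-fold; the mode exists for structural
exploration).

## Parameters

All inputs live in `rbpm_cea.parameters` with base value, range, kind and
units; probabilities are per-day unless labelled per-14-day.  Key values:
daily BP outcomes 0.962 / 0.03 / 0.008 / 7e-5 / 1.9e-5 (the published
values sum to 1.000089, so the normotensive probability is treated as the
simplex slack and absorbs the residual; the severe-BP range is implemented
as 0.006–0.012 because its printed range "0.0060–0.0012" cannot bracket
the base value); acknowledgment 0.65 / 0.86 (RBPM mild/severe) and
0.04 / 0.60 (usual care); readmission costs $17,549; program $139; cuff
$50; nurse $127,374/yr ÷ 900 patients = $141.53 (rounded half-up to
cents); outpatient visit $145; willingness to pay $100,000/QALY.  The
medication-titration probability (0.30 per 14 days) is carried as a
microsimulation annotation only — medication costs are excluded — and the
mild-BP acknowledgment probabilities have no transition-structure role.

**Utility weights are not published.**  Package defaults: 1.0
(normotensive), 0.98 (mild), 0.90 (severe-range, recognized or not), 0.60
(morbidity) per day; after day 14, 50% of survivors have persistent
hypertension at a 0.02 utility decrement, the RBPM arm recovering part of
it (the calibrated uplift, ≈ 0.0042, reflecting evidence that remote
monitoring improves BP control in the first postpartum year).  All are
configurable; none is varied in the PSA.

## Calibration

Fixed costs plus event costs at the published flows cannot reach the
published per-arm totals ($330.53 + 0.01 × $17,549 ≪ $2987.92), and the
published "QALYs over 14 d" figures are dimensionally inconsistent with a
1-year QALY horizon — the reference totals embed structure that was never
published.  Rather than hide fudge factors, `calibrate_base_case` fits
three named constants, deterministically and in order:

1. **Acknowledgment scalings** (root-finding, Brent): cumulative 14-day
   readmissions = 0.01 / 0.05.  Fitted values ≈ 0.0152 (RBPM) / 0.145
   (usual care).
2. **Background-care costs** (residual solve): per-arm additive constants
   (≈ $2457 RBPM, $3169 usual care) so total costs equal $2987.92 /
   $4213.99.  These are interpretable as routine postpartum care spending
   not itemised by the reference analysis.  A multiplicative variant
   (scaling event costs instead) is available but not the default: it
   would imply an effective cost of ≈ $242,000 per RBPM readmission —
    13.8 × the published readmission cost — and would amplify
   readmission-probability uncertainty asymmetrically in the PSA.
3. **RBPM utility uplift** (linear solve): between-arm QALY difference =
   $1226.07 / $630,093.70 per QALY = 0.0019458, the gain implied by the
   published incremental results.

The constants persist to JSON and are **frozen during every downstream
analysis**; recalibrating at each swept point would erase the sensitivity
being measured.

## Sensitivity analyses

One-way thresholds bisect the sign change of
NMB(RBPM) − NMB(usual care) after an 11-point pilot scan of the search
interval (all sign-change brackets are reported if there are several);
absolute tolerances are $0.01 for costs and 1e-4 for probabilities.
Default search intervals are [0, 1.5 × high] for costs and [0, 1] for
probabilities — deliberately wider than the published plausibility ranges,
since the reference thresholds lie outside their own ranges.  Two-way
analysis evaluates the NMB decision per grid cell.  NMB ties break toward
usual care (the incumbent).

## Probabilistic sensitivity analysis

Distributions are fitted by method of moments with the mean pinned to the
base value and the published range read as a central 95% interval
(sd = width/3.92; a min/max-uniform alternative, sd = width/√12, is
available).  Costs are gamma; probabilities beta (variance clamped to
0.99 × m(1−m) with a logged warning if the range implies an infeasible
beta).  Varied inputs: the five BP outcome probabilities (normotensive
re-absorbs the simplex residual after sampling, preserving sampled tails),
the four acknowledgment probabilities, both per-14-day readmission
probabilities (configurable off), and the five unit costs — all
independent.  Per trial the acknowledgment scaling is re-solved by
vectorized bisection (60 iterations) against the trial's sampled
readmission targets; targets above the mechanistic ceiling (possible when
the sampled severe-BP incidence is low) saturate and are counted.  The
engine evolves all trial cohorts simultaneously with hand-unrolled state
updates proven equivalent to the transition-matrix path in the test suite,
and is bit-reproducible given the seed.  Default 100,000 trials (≈ 4 s,
one CPU).  Summaries: acceptability fraction at a WTP (ties count against
RBPM), the acceptability curve over a WTP grid, and the CE-plane sample
moments with a chi-square(2, 0.95) confidence ellipse (degeneracy is
judged on the correlation, since the two axes carry different units).

## Microsimulation

`rbpm_cea.microsim` draws individual daily trajectories from the same
transition rows (inverse-CDF sampling, one uniform per patient-day) and
accrues costs/QALYs under the same rules, giving (i) an independent
brute-force oracle — cohort expectations must match 200,000-patient
simulation means within three standard errors for cost, QALYs,
readmissions and deaths — and (ii) exportable synthetic patient-day
datasets.  It reproduces exactly the homogeneous-cohort world of the
cohort model: no patient-level covariates, no heterogeneity, no
behavioural response.  Passing oracle tests therefore validates the
implementation, not the model's fidelity to any real population.

## Known limitations

* **The published one-way thresholds do not exist in the calibrated
  model.**  After calibration, the WTP-weighted QALY advantage of RBPM
  ($194.59) exceeds its fixed-cost disadvantage ($185.53), so the NMB
  difference is positive even at a readmission cost of zero: no
  readmission-cost threshold can exist, for any calibration whose event
  costs scale with the readmission cost and which matches the published
  totals and ICER.  Likewise, lowering the RBPM severe-BP acknowledgment
  rate *reduces* RBPM readmissions and costs in any recognition-driven
  structure, so no acknowledgment threshold arises on [0, 1].  The
  published totals, ICER, and thresholds are mutually inconsistent under
  one tree (a tree reproducing the thresholds would need ΔC ≈ $530 and
  ΔQALY ≈ 0.00084, contradicting the published ΔC = $1226.07); this
  package reproduces the base-case totals and ICER and documents the
  discrepancy rather than forcing both.
* The PSA acceptability at $100,000/QALY computes to ≈ 97.2%, not the
  reference 99.28%; the gap traces to the distribution conventions
  (especially the very wide published range 0.00–0.15 for the RBPM
  readmission probability) and the unpublished tree structure above.
* The published "$145.00 incremental cost per readmission averted" is not
  reproduced: it does not follow from the published per-arm rows
  (ΔC/ΔReadmissions = $1226.07/0.04, and the model computes a *saving* of
  $30,651.75 per averted readmission); $145 coincides with the outpatient
  visit cost.
* Horizon is one year; long-term cardiovascular sequelae, medication
  costs, and hospital-perspective (revenue) analyses are out of scope.
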