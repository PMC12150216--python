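# rbpm-cea

Cost-effectiveness model of **remote blood pressure management (RBPM)
versus usual care for postpartum hypertension**.

Hypertensive disorders of pregnancy are a leading cause of postpartum
emergency-department visits and readmissions, most of which occur in the
first two weeks after delivery — usually before the first scheduled
outpatient visit.  RBPM programs give patients a home BP cuff, have them
upload twice-daily readings, and staff a clinician (modelled as 1.0 FTE
nurse practitioner per 900 patients/year) to respond to abnormal values.
This package asks the health-economic question: **does the program pay for
itself by averting $17,549 readmissions, and at what parameter values does
the answer flip?**  It is written for health-services researchers and
program planners who want to rerun the analysis under their own costs,
acknowledgment rates, and readmission risks.

## The model

A Markov cohort model over fourteen 1-day cycles with six states:
normotensive, mild-range BP, unrecognized severe-range BP, readmitted
(one-day tunnel), severe morbidity, and death.  Each day a patient draws a
BP outcome `(p_norm, p_mild, p_sev, p_morb, p_death)`; severe-range mass
splits on whether the reading is *acknowledged* by the care team —
acknowledged severe BP is readmitted, unacknowledged severe BP carries
extra preeclampsia death and escalated morbidity hazards until caught.

Outcomes per strategy arm:

* **cost** — fixed strategy costs (program + cuff + nurse, or one
  outpatient visit) plus $17,549 per readmission/morbidity event, plus a
  calibrated per-arm background-care cost;
* **QALYs** — daily state utilities over the 14 days plus a 1-year
  extrapolation in which 50% of survivors have persistent hypertension
  (utility decrement 0.02, partially recovered in the RBPM arm);
* **decision statistics** — incremental cost ΔC, incremental effectiveness
  ΔE, ICER = ΔC/ΔE with dominance classification, and net monetary benefit
  NMB = λ·E − C at willingness to pay λ = $100,000/QALY.

Because the reference analysis's full decision tree was never published,
an explicit `calibrate_base_case` step root-finds three interpretable
constants (per-arm acknowledgment scaling, per-arm background-care cost,
RBPM utility uplift) so the base case reproduces the published totals; all
sensitivity analyses run with those constants frozen.  See
`docs/methods.md` for the full specification, assumptions, and known
limitations.

Modules: `parameters` (inputs, validation, beta/gamma PSA distributions),
`markov` (transition structure, cohort evolution, accrual, calibration),
`cea` (ICER/dominance/NMB), `sensitivity` (one-way thresholds, two-way
grids), `psa` (vectorized Monte Carlo, CEAC, CE-plane ellipse), `microsim`
(patient-level simulation: synthetic-data generator and brute-force oracle
for the cohort expectations).

## Worked example

```bash
$ rbpm-cea basecase --out out/base
decision: rbpm (dominant(rbpm)); costs rbpm=2987.92 usual_care=4213.99
```

RBPM costs $2987.92 per patient over 14 days versus $4213.99 under usual
care while readmitting 1% versus 5% of patients and gaining 0.0019 QALYs —
RBPM *dominates* (cheaper **and** more effective).  The written `cea.json`
reports ΔC = $1226.07, the ICER of $630,093.70 per QALY that usual care
would effectively pay per QALY forgone, and a cost **saving** of
$30,651.75 per readmission averted.

```bash
$ rbpm-cea oneway --parameter c_readm --out out/oneway
c_readm: decision constant (rbpm) over (0.0, 26601.0)
```

In this calibrated model the decision never flips as the readmission cost
varies: the $194.59 WTP-weighted QALY advantage of RBPM already exceeds
its $185.53 fixed-cost disadvantage, so RBPM stays preferred even with
free readmissions (see `docs/methods.md` on why this differs from the
reference report's printed thresholds).

```bash
$ rbpm-cea psa --n 10000 --seed 1 --out out/psa
acceptability at WTP 100000: 0.9718
```

Across 10,000 Monte Carlo draws of all costs and probabilities, RBPM has
the higher net monetary benefit in 97.2% of trials.  `out/psa` also
contains the per-trial CE-plane cloud, the acceptability curve over WTP
0–200k, and the 95% confidence ellipse parameters.

Scenario overrides live in a small YAML file, e.g. a $150 Bluetooth cuff:

```yaml
scenarios:
  bluetooth_cuff:
    c_cuff: {base: 150}
```

```bash
rbpm-cea basecase --config scenarios.yaml --scenario bluetooth_cuff --out out/bt
```

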