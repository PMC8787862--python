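# rtmicrocost

Micro-costing and causal comparison of two rotational intensity-modulated
radiotherapy (IMRT) techniques — Volumetric Modulated Arc Therapy (VMAT)
and helical tomotherapy (HT) — for high-risk prostate cancer with pelvic
lymph-node irradiation. The package is aimed at health economists and
radiation-oncology researchers who want a tested, reproducible pipeline
for:

* **bottom-up (micro-)costing** of IMRT preparation and delivery from
  per-patient resource-use logs (staff minutes per role, machine minutes),
  valued with hourly wages and straight-line, undiscounted equipment
  amortization, including annual machine QC / internal-maintenance labor;
* **stabilized inverse-probability-of-treatment weighting (IPTW)** to
  compare the non-randomized arms, with standardized-difference balance
  diagnostics (binary, continuous and generalized multilevel forms);
* **outcome models** adjusting for plan type: weighted least squares for
  total cost and a weighted proportional-odds (cumulative logit) model for
  collapsed CTCAE toxicity grades (0 / 1 / 2 / 3–4), both with robust
  standard errors;
* **uncertainty**: arm-stratified percentile bootstrap (rank-trimmed CI)
  and one-way ±20% tornado sensitivity analysis;
* a **seeded synthetic cohort generator** emulating the study structure
  (106 VMAT vs 49 HT patients, confounded treatment assignment, 34-fraction
  SIB vs 40-fraction sequential plans, a per-session learning curve, and
  ordinal acute/late GI, GU and sexual toxicity), so the whole pipeline is
  exercisable without any patient data.

## Model summary

The propensity score `e(x) = P(HT | x)` is a logistic regression on age,
ECOG performance status, cT stage (contrasts against cT1), cN stage and
capped PSA. Each patient receives the stabilized weight

```
w_i = P(HT) / e(x_i)            (HT arm)
w_i = P(VMAT) / (1 - e(x_i))    (VMAT arm)
```

so the weighted pseudo-population keeps the original sample size. Cost per
patient is the sum over logged events of `minutes/60 × hourly rate`, where
labor rates are annual full gross wage / workable yearly hours, and machine
rates are `(price/lifespan + maintenance + annual QC/IM labor) / annual
operating hours` (12-year accelerator and 5-year TPS lifespans; the HT
price includes its integrated TPS). Toxicity uses the proportional-odds
model `P(grade ≤ k | arm, plan) = expit(c_k − β·VMAT − γ·sequential)`.

## Worked example

```python
import pandas as pd
import rtmicrocost as rtm

config = rtm.default_cohort_config(seed=1)          # 106 VMAT / 49 HT
patients, events, toxicity = rtm.generate_cohort(config)
unit_costs = rtm.default_unit_costs()
arms = patients.set_index("patient_id")["arm"]
breakdowns = rtm.cost_breakdowns(events, arms, unit_costs)

ps = rtm.PropensityModel(patients).fit()
print(ps.balance_table().round(3).to_string(index=False))
```

```
         covariate       kind  unweighted_d  weighted_d
               age continuous         0.340      -0.068
performance_status     binary         0.239      -0.010
         c_t_stage multilevel         0.367       0.107
         c_n_stage     binary         0.461      -0.019
               psa continuous         0.127      -0.046
```

The raw cohort is confounded (|d| up to 0.46); weighting shrinks every
standardized difference toward zero. Bootstrapping the weighted mean total
cost per arm (1,000 iterations, 2.5% trimmed per tail):

```python
weights = pd.Series(ps.stabilized_weights, index=patients["patient_id"].to_numpy())
w = weights.reindex(breakdowns["patient_id"]).to_numpy()
print(rtm.bootstrap_by_arm(breakdowns, w, rtm.BootstrapConfig(1000, seed=1)))
```

```
 arm    mean  ci_low  ci_high  iterations  ci_level
VMAT 2493.69 2412.63  2578.54        1000      0.95
  HT 3160.16 2934.09  3375.95        1000      0.95
```

HT treatment costs roughly €600 more per patient than VMAT in this
simulated cohort, driven almost entirely by accelerator occupancy during
the treatment sessions. The adjusted effect estimates:

```python
est = rtm.weighted_linear_model(breakdowns["total_cost"], ..., weights=w)
# adjusted HT - VMAT cost difference: 613 EUR (SE 114, p 7.3e-08)

grades = rtm.grade_table(toxicity, patients, "GU", "acute")
# acute GU log-OR (VMAT vs HT, worse grades): 0.56 (SE 0.38, p 0.143)
```

The positive log-odds ratio reflects the generator's acute genito-urinary
effect (VMAT worse); at n = 147 a single simulated cohort does not always
reach significance.

The full pipeline (simulate → cost → weight → analyze → bootstrap →
tornado, with a run manifest) is also available from the shell:

```
rtmicrocost run --seed 1 --out out/
rtmicrocost simulate --seed 1 --out sim/
rtmicrocost weight --cohort sim/patients.csv --out weights/
```

## Layout

```
src/rtmicrocost/
  config.py       cohort-generator configuration (covariates, assignment,
                  toxicity, timing models)
  cohort.py       synthetic cohort generation (patients, resource use, toxicity)
  costing.py      unit costs, per-patient breakdowns, weighted summaries
  weighting.py    PropensityModel/Results, stabilized IPTW, standardized d
  outcomes.py     grade collapsing, weighted ordinal + linear effect models
  uncertainty.py  percentile bootstrap, one-way tornado sensitivity
  defaults.py     calibrated default parameters (the study conditions)
  pipeline.py     end-to-end orchestration with manifest + report rendering
  cli.py          `rtmicrocost` command-line interface
docs/methods.md   modeling assumptions, calibration and limitations
```
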