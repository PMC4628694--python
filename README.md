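# icushock

Rule-based septic-shock onset detection and 7-day mortality modelling from
routinely recorded ICU series, packaged as a reusable, fully tested
pipeline with a synthetic-cohort generator for desk-scale validation.

## What it does

Given per-patient irregularly sampled clinical series (15 canonical
variables: SBP, DBP, MAP, HR, RR, CVP, CO, T, pH, creatinine, glucose,
lactate, hematocrit, WBC, SpO2), timestamped intravenous fluid events and
outcomes, the pipeline:

1. **filters** the cohort (at least 10 HR/T/SBP/RR values, 2 WBC values,
   ICU stay of at least 48 h);
2. **detects septic-shock onset** with sample-and-hold interval logic:
   SIRS abnormality episodes (2-of-4 criteria by default, starts
   backtracked to the first contributing abnormal measurement, merged when
   less than 6 h apart, kept when longer than 5 h), prolonged hypotension
   (SBP < 90 mmHg for at least 30 min), and fluid qualification (> 600 mL
   from 1 h before an episode to its midpoint); the earliest
   sepsis-induced hypotension episode marks the onset, and records with
   fewer than two prolonged hypotension episodes are considered to have no
   shock episode;
3. **extracts 135 indexes** — 9 statistics (mean, std, min, max, median,
   kurtosis, skewness, OLS slope, delta) for each of the 15 variables —
   from the first 48 h after onset, labels patients NS when death occurs
   within 7 days of onset, and mean-imputes missing entries;
4. **screens** every feature between survivors and nonsurvivors with the
   two-sided Wilcoxon rank-sum test plus Benjamini–Hochberg q-values;
5. **fits the mortality model**: elastic-net-penalized linear regression
   (hand-rolled cyclic coordinate descent, warm-started lambda path),
   3/4/5-fold cross-validation with the one-standard-error rule, iterative
   VIF > 5 pruning, unpenalized refit, and stratified 5-fold CV AUC
   reported as mean ± sd.

A seeded synthetic-cohort generator (`icushock.synthetic`) emulates the
statistical structure the analysis assumes — irregular sampling, SIRS-type
abnormality periods, decoy and fluid-qualified hypotension episodes, and
configurable survivor/nonsurvivor effects — with full ground truth, so
every stage is testable without access to a clinical database.

## CLI

```bash
# one reproducible end-to-end run on a simulated cohort
icushock run-all --seed 1 --out-dir runs/demo

# or stage by stage
icushock simulate --seed 1 --out-dir runs/demo
icushock filter --cohort-dir runs/demo --out-dir runs/demo
icushock detect-onset --cohort-dir runs/demo --out-dir runs/demo
icushock extract-features --cohort-dir runs/demo \
    --onsets runs/demo/onsets.csv --out-dir runs/demo
icushock screen --features runs/demo/features.csv --out-dir runs/demo
icushock fit --features runs/demo/features.csv --out-dir runs/demo
icushock evaluate --features runs/demo/features.csv --out-dir runs/demo
```

All commands accept `--config config.yaml` (see `RunConfig.to_dict()` for
the schema; defaults equal the published rule thresholds).  `run-all`
writes a `manifest.json` with the config hash and per-stage attrition;
re-running with an identical config reproduces byte-identical tables.

Cohort files are plain CSV: `vitals.csv`
(`patient_id,variable,time_h,value`), `fluids.csv`
(`patient_id,time_h,volume_ml`) and `outcomes.csv`
(`patient_id,age_years,icu_stay_h,death_time_h`), all times in hours from
ICU admission.

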