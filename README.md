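# sichscore

Risk scoring and evaluation toolkit for post-thrombolysis symptomatic
intracerebral hemorrhage (SICH) after intravenous tPA in acute ischemic
stroke.

The package implements:

* **riskscore** — the 12-point SITS SICH risk score (nine pretreatment
  variables with fixed integer weights) and a 15-point extended score
  that adds an OCSP stroke-syndrome component: +3 points (configurable)
  for a total anterior circulation infarct (TACI), and a zeroing rule for
  posterior circulation infarcts (POCI). Scores map to LOW / AVERAGE /
  ELEVATED strata (SITS: 0–2 / 3–5 / ≥6; extended: 0–3 / 4–7 / ≥8).
* **ocsp** — the TACI/PACI/POCI/LACI/UNCERTAIN syndrome enum, a
  rule-based classifier over a structured symptom checklist, a
  multi-rater discrepancy resolver, and unweighted Cohen's kappa.
* **outcomes** — SICH adjudication from structured follow-up records
  (serial NIHSS, imaging findings, death) under the NINDS, ECASS II and
  SITS-MOST definitions.
* **evalstats** — univariate logistic regression (odds ratio per score
  point, IRLS), Hosmer–Lemeshow calibration, AUC with DeLong or
  bootstrap confidence intervals, the DeLong paired test for correlated
  AUCs, 3×3 reclassification tables, and the categorical net
  reclassification improvement (NRI) with its asymptotic z-test.
* **synthetic** — a seeded cohort generator calibrated to published
  marginal covariate summaries, with a logistic outcome model whose
  intercept is solved to hit a requested marginal SICH rate, and
  constructive follow-up records that adjudicate exactly to the
  simulated labels.
* **cli / io** — CSV readers/writers with row-level validation and a
  `sichscore` command-line entry point.

## CLI

All stochastic commands require an explicit `--seed` and are
bit-reproducible.

```bash
# generate a synthetic cohort + follow-up + truth labels
sichscore simulate --n 548 --seed 7 --definition ecass2 --out-prefix sim

# compute both scores and risk strata
sichscore score --in sim_cohort.csv --out scored.csv [--taci-weight 3]

# adjudicate SICH under all three definitions
sichscore adjudicate --cohort sim_cohort.csv --followup sim_followup.csv \
    --out verdicts.csv

# paired evaluation of the two scores for one definition
sichscore evaluate --scored scored.csv --verdicts verdicts.csv \
    --definition ecass2 --seed 1 --out report.json

# full text/JSON comparison report across all three definitions
sichscore compare --scored scored.csv --verdicts verdicts.csv --seed 1

# OCSP classification and inter-rater agreement
sichscore classify --in symptoms.csv --out ocsp.csv
sichscore agreement --in ratings.csv
```

`simulate` accepts `--config cfg.yaml` to override any generator
parameter (covariate means/SDs, OCSP probabilities, the outcome-model
slope `beta`, target event rates, ...).

## File formats

* Cohort CSV: `patient_id, age, nihss_baseline, glucose, glucose_unit
  {mgdl|mmol}, sbp, weight_kg, ott_min, htn_history {0,1}, antiplatelet
  {none|aspirin|aspirin_clopidogrel}, ocsp {TACI|PACI|POCI|LACI|UNCERTAIN}`.
  Glucose may be given in either unit; the 180 mg/dL cutoff is applied
  after normalization (1 mmol/L = 18.016 mg/dL).
* Follow-up CSV (long format): `patient_id, event_type
  {nihss|scan|death}, hours, value` where `value` is an NIHSS score or an
  ICH type token (`HI1|HI2|PH1|PH2|PHr1|PHr2|none`).
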