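# costas

A clinically oriented scoring scale for deciding which patients with
aneurysmal subarachnoid hemorrhage (SAH) and symptomatic cerebral vasospasm
should be considered for invasive intra-arterial spasmolysis.

Intra-arterial spasmolysis (catheter-delivered nimodipine into spastic
cerebral arteries) can be life-saving, but it is an invasive procedure
performed outside the ICU, and only a subgroup of vasospasm patients
benefits. The scale summarizes a patient's holistic clinical state at the
moment of decision as a single 0–18 triage score built from nine bedside
parameters:

| parameter | bands | points |
|---|---|---|
| age | ≥65 years | 0–1 |
| cigarette smoking | smoker | 0–1 |
| intracranial arterial atherosclerosis | ≥50% stenosis | 0–1 |
| BMI (kg/m²) | 18.5–24.9 / 25–29.9 / ≥30 | 0–2 |
| eGFR (mL/min) | 45–59 / 30–44 / <30 | 0–2 |
| PaO₂/FiO₂ (mmHg, Berlin ARDS) | 201–300 / 101–200 / ≤100 | 0–3 |
| PEEP (cm H₂O) | 5–9 / 10–14 / ≥15 | 0–3 |
| noradrenaline (mg/h) | none / ≤0.5 / 0.6–1.9 / ≥2 | 0–3 |
| AI vasospasm probability | ≤50% / 51–74% / ≥75% | 0–2 |

The total is the sum of the nine parameter points, `S = Σᵢ sᵢ ∈ [0, 18]`;
higher totals flag sicker patients. No treat/no-treat threshold is defined
on the total — the scale reports, clinicians decide.

Around the scale the package implements:

- **screening** — the trigger rules for suspected vasospasm (transcranial
  Doppler mean velocity >190 cm/s or a ≥50% rise over the prior
  measurement) and for delayed cerebral ischemia (new focal deficit or a
  GCS drop ≥2 on the total or any component, lasting ≥1 h, not otherwise
  explained);
- **dosing** — noradrenaline infusion preparation (the standard 5 mg/5 mL
  vial diluted to 50 mL gives 0.1 mg/mL), pump-rate arithmetic, and the
  bridge between institutional mg/h dosing and the literature's μg/kg/min
  shock-severity bands;
- **risk model** — a kernel-SVM classifier (scikit-learn estimator API)
  predicting symptomatic-vasospasm probability from admission features
  (sex, age, Hunt & Hess, Fisher, BNI, comorbidities, anticoagulation,
  operation duration, treatment modality), evaluated by stratified holdout
  and k-fold cross-validation;
- **synthetic cohorts** — a generator emulating an 87-patient SAH cohort
  (45 surgical / 42 endovascular) with a planted logistic feature–outcome
  association, used as training and test harness since no study data are
  deposited.

## Worked example

Score a ventilated 70-year-old smoker (BMI 28, eGFR 50 mL/min, P/F 250
mmHg, PEEP 8 cm H₂O, noradrenaline 1.0 mg/h, model risk 60%):

```python
from costas import validate_record, total_score, render_report

rec = validate_record({
    "patient_id": "demo-001", "age": 70, "smoker": True,
    "iaa_stenosis_pct": 30.0, "bmi": 28.0, "egfr": 50.0,
    "pf_ratio": 250.0, "peep": 8.0, "noradrenaline_mg_per_h": 1.0,
    "ai_risk_prob": 0.60, "weight_kg": 75.0,
})
print(render_report(total_score(rec), risk_prob=rec.ai_risk_prob).to_text())
```

```
COSTAS triage report - patient demo-001
scale version: costas-1.0
----------------------------------------------------------
age            >=65 years                   1 pt
smoking        smoker                       1 pt
iaa            <50% stenosis                0 pt
bmi            overweight                   1 pt
egfr           low risk                     0 pt
pf_ratio       mild                         1 pt
peep           mild                         1 pt
noradrenaline  moderate risk                2 pt
ai_risk        moderate risk                1 pt
----------------------------------------------------------
TOTAL                                       8 / 18
model vasospasm probability: 0.600
```

Age, smoking, overweight, mild oxygenation impairment and mild PEEP earn a
point each; the 1.0 mg/h noradrenaline requirement falls in the moderate
band (2 points) as does the 60% model probability (1 point), for a total of
8 of 18.

The same machinery is available from the shell:

```sh
$ costas dose --mg-per-h 1.0 --weight-kg 75
{"costas_label": "moderate risk", "costas_points": 2, "dose_mg_per_h": 1.0,
 "dose_ug_per_kg_min": 0.2222, "pump_rate_ml_per_h": 10.0,
 "shock_band": "moderate", "shock_flags": []}
```

(1.0 mg/h at the standard 0.1 mg/mL preparation runs the pump at 10 mL/h
and corresponds to 0.22 μg/kg/min — moderate shock-range support.)

Other subcommands: `costas score patients.csv`, `costas screen obs.csv`,
`costas cohort --n 87 --seed 1 --out cohort.csv`, `costas train`,
`costas predict`, `costas evaluate`. Alternative band tables load from
YAML via `--table`.

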