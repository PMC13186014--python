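# Methods

## The scale

The score is a deliberately simple additive point system. Nine parameters
are each mapped through fixed clinical bands to an integer number of
points, and the total is their sum, 0–18. The parameters fall into three
groups by weight: binary risk markers worth one point (age ≥65, cigarette
smoking, intracranial arterial atherosclerosis with ≥50% stenosis of an
intracranial vessel on any accepted modality), three-band markers worth up
to two points (BMI by the WHO weight classes; eGFR by the KDOQI
chronic-kidney-disease risk bands; the machine-learning vasospasm
probability), and four-band markers worth up to three points (P/F ratio by
the Berlin ARDS severity classes; PEEP; noradrenaline requirement in the
institution's mg/h bands). The per-parameter maxima (1, 1, 1, 2, 2, 3, 3,
3, 2) sum to 18.

The scale is additive and each parameter's band mapping is monotone in
clinical severity, so the total is monotone too: worsening any single input
can never lower the score. This is asserted as a test invariant.

No decision threshold is defined on the total. The scale is a triage
summary for the spasmolysis decision, not a prediction of outcome, and the
package deliberately offers no cut-off.

### Band edges and gap closing

The published bands are printed with one decimal of precision and a few
gaps. Because every scored quantity is continuous, the package reads the
printed edges as half-open real intervals and closes the gaps with
documented choices, each conservative toward severity where ambiguity
exists:

- **BMI** "25–29.9" becomes [25, 30); values below 18.5 (underweight, not
  covered by the published bands) score 0 and carry an
  `underweight_unspecified` flag so reports stay transparent.
- **eGFR** at or above 60 mL/min is better than the lowest published risk
  band; it scores 0 with an `above_kdoqi_bands` flag.
- **P/F** exactly 100 mmHg sits between "less than 100" and "101 to 200";
  it is assigned 3 points (severe). Values above 300 score 0.
- **PEEP** below 5 cm H₂O scores 0; above the printed 20 cm H₂O ceiling it
  keeps 3 points with a `peep_above_band` flag.
- **Noradrenaline** gaps (0.5–0.6 and 1.9–2.0 mg/h) close toward the
  higher band: (0, 0.5] → 1, (0.5, 2) → 2, [2, ∞) → 3. Exactly zero is its
  own band.
- **AI probability** "51–74%" becomes (0.50, 0.75) so all of [0, 1] is
  covered: [0, 0.5] → 0, (0.5, 0.75) → 1, [0.75, 1] → 2.

Because the closures differ between parameters (some bands are
upper-inclusive, some lower-inclusive, one is a single point), the scoring
table stores each band as an interval with explicit endpoint-closure
flags. Table construction verifies that each parameter's bands tile
[0, ∞) with every edge claimed by exactly one side. The table serializes
to YAML, so a multicenter recalibration is a config change; the shipped
default is the published scale.

The test suite checks the table-driven scorer against an independently
written oracle — literal comparison chains transcribed from the published
cut-offs — on a dense grid of roughly 10⁵ values across all parameters.

### Record validation

Inputs are validated by a pydantic model with fixed units (years, percent,
kg/m², mL/min, mmHg, cm H₂O, mg/h, kg). Design choices where the inputs
are genuinely ambiguous:

- Ventilation fields travel together: `pf_ratio` and `peep` are both
  present (ventilated) or both absent (spontaneously breathing, in which
  case both ventilation parameters score 0 — a patient not on a ventilator
  has no ventilation burden).
- Atherosclerosis is accepted as a stenosis percentage or as an
  adjudicated boolean, since TCD or intraoperative assessment may
  establish ≥50% stenosis without producing a number.
- Smoking is a single boolean. Whether this means current smoking or a
  pack-year criterion is not specified by the scale's definition; the
  package stores the clinician's adjudication and documents the
  ambiguity here.
- Ages are whole years; fractional ages floor (you are 64 until your 65th
  birthday).
- BMI may be derived as weight/height² when not given directly.

## Screening rules

Suspected vasospasm: TCD mean flow velocity strictly above 190 cm/s
(exactly 190 does not trigger), or a relative rise of at least 50% over
the previous measurement of the same vessel (inclusive at exactly 50%). A
previous velocity of zero makes the relative rule undefined; the absolute
rule is evaluated first and an error is raised only if it is also silent.

DCI-attributable deterioration: a newly present focal deficit
(hemiparesis, aphasia, apraxia, hemianopsia, neglect) or a GCS drop of at
least 2 points on the total or on any single component (eye, verbal, motor
on either side), sustained for at least one hour, and not attributable to
another cause. Attribution is a clinical adjudication (imaging,
laboratory) supplied as an input flag, never computed. The GCS total uses
the better motor side, so a unilateral motor drop can trigger the
component rule while the total is preserved — which is precisely why the
component rule exists.

Induced-hypertension MAP targets (80–90 mmHg, >100 mmHg if spasm
persists) are recorded as protocol constants but gate no rule: the
published protocol uses them to steer therapy, not to define events.

## Dosing

The institutional preparation is a 5 mg/5 mL noradrenaline vial diluted to
50 mL with 0.9% saline: 0.1 mg/mL, so pump rate in mL/h is ten times the
dose in mg/h. The bridge to the weight-based literature scale is
`μg/kg/min = mg/h × 1000 / 60 / weight`. The literature shock bands
(<0.1 mild, 0.1–0.3 moderate, 0.3–0.5 severe, >0.5 refractory μg/kg/min)
are reported for context only — boundary values fall to the higher
severity side, consistent with the printed "<0.1" lower band — while the
scale's noradrenaline points always come from the institutional mg/h
bands. No derivation of the mg/h bands from the μg/kg/min bands at a
reference weight is assumed; the published standardization is mg/h, and
the bands are taken as given.

## Risk model

The vasospasm-risk predictor is a kernel support-vector classifier over a
fixed feature schema: one-hot encodings of sex (2 levels),
anticoagulation (none/ASA/DOAC/antiplatelet/combination) and treatment
modality (surgical/endovascular); 0/1 indicators for the three
comorbidity groups (arterial hypertension, cardiovascular, pulmonary;
"none" is the all-zero configuration); the Hunt & Hess (1–5), Fisher
(1–4) and BNI (1–5) grades as integers; and age and operation duration
standardized with training-set statistics. Encoded length 17. Categorical
levels are fixed by the schema, not learned from data, so an unknown
level always errors by name and the encoding is identical regardless of
which levels a training cohort happens to contain.

Evaluation follows the holdout-plus-cross-validation protocol: a
stratified 25% holdout (a fresh model fitted on the remainder and scored
on the holdout) and stratified 5-fold cross-validation over the full
cohort, both recorded as fitted attributes; the deployed model is then
refitted on all rows. Kernel (RBF), regularization (C = 1), bandwidth
(`gamma="scale"`, the variance heuristic), holdout fraction and fold
count are estimator parameters — the method description names the
classifier family but none of its hyperparameters, so these defaults are
package choices, exposed as configuration. Probabilities come from Platt
scaling (sigmoid calibration on internal cross-validated decision
values), the standard score-to-probability mapping for SVMs. All
randomness (holdout split, fold shuffling) is controlled by a single
`random_state`.

The model trained and validated here sees only synthetic cohorts. The
originally reported 61–86% accuracy was measured on an institutional
87-patient cohort that is not deposited; it is context, not a
reproducible quantity, and nothing in this package claims clinical
validity for a synthetically trained model.

## Synthetic cohort generator

The generator emulates the structure of that cohort: default n = 87 with
a 45/42 surgical/endovascular split, admission features and bedside
scoring fields drawn from clinically plausible marginals (SAH skews
female, ~0.65; age ≈ N(55, 12²) clipped to 18–90; Fisher grades skew high
in a cohort that bled, P(4) = 0.4; ~55% ventilated with P/F ≈ N(230, 80²)
and PEEP ≈ N(8, 3²); ~60% on noradrenaline with log-normal dose around
0.5 mg/h; craniotomies run longer than coiling, log-normal around 180 vs
120 min). These marginals are documented package choices, not estimates
of any real cohort, and no covariance structure beyond the outcome model
is claimed.

The binary symptomatic-vasospasm outcome is drawn from a logistic model:
baseline prevalence 0.30 (the ballpark symptomatic-vasospasm rate after
SAH) at the feature centers, plus planted log-odds contributions per unit
of centered feature — defaults 0.9 per Fisher grade, 0.5 per Hunt & Hess
grade, −0.03 per year of age (vasospasm risk is highest in younger SAH
patients), 0.004 per minute of operation, 0.4 for surgical treatment.
Because the generator knows each patient's true probability p, it reports
the implied prevalence (mean p) and the Bayes-optimal accuracy
E[max(p, 1−p)] — the ceiling any classifier can reach. The test suite
requires the SVM's 5-fold CV accuracy on an n = 1000 cohort to fall
within 5 percentage points of that ceiling, and a label-permuted cohort
to fall back to the majority-class rate.

What the synthetic harness does *not* carry over from real data:
measurement error and missingness patterns, correlated comorbidity
structure, nonlinear or interaction effects on the outcome, and cohort
drift over time. Passing tests therefore demonstrate that the machinery
is correct and can recover a known signal at known strength — not that
the model, the marginals or the planted effects describe real SAH
patients.

## Numerical and I/O choices

- Band lookup is a linear scan over at most five intervals per parameter;
  at these sizes a bisection structure would add complexity without
  measurable benefit.
- CSV I/O uses shortest-round-trip float rendering on write and the
  round-trip float parser on read, so CSV ↔ JSON conversions are lossless
  to the bit.
- The decimal separator is always the dot; middle-dot typography in
  printed band edges is typography, not a data format.
- Reports render deterministically (sorted JSON keys), so byte-identical
  re-rendering is a test invariant; the JSON report parses back into the
  full score structure.
- CLI exit codes: 0 success, 3 validation failure, 4 I/O failure.

## Problem sizes used in the checks

The shipped verification uses the sizes at which the properties are
informative yet instantaneous on a single CPU: ~10⁵ grid points for the
band oracle, 10 000 randomized records for the range property, n = 1000
(training) and n = 10 000 (prevalence convergence) for the synthetic
cohorts. The acceptance script's headline computation — the worst-band
patient against the table maxima — is exact and runs in milliseconds.

## Known limitations

- The scale itself is a prototype: its weights are expert-assigned, not
  fitted, and multicenter validation is explicitly future work.
- The noradrenaline severity bands lack a consensus basis; the mg/h bands
  are institutional practice, and the μg/kg/min literature bands are
  approximate.
- The risk model's clinical accuracy cannot be reproduced or audited
  without the original cohort; everything here validates methodology on
  synthetic data only.
- Single-boolean smoking and once-per-patient atherosclerosis assessment
  are simplifications of ambiguous definitions, documented above.
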