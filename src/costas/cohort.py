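"""Synthetic aneurysmal-SAH cohort generator.

Emulates the structure of the study cohort behind the risk model: 87
patients over two years, 45 treated surgically and 42 endovascularly, with
admission features (sex, age, Hunt & Hess, Fisher, BNI, comorbidities,
anticoagulation, operation duration) and the bedside quantities the scoring
scale consumes (smoking, intracranial stenosis, BMI, eGFR, ventilation
metrics, noradrenaline dose, weight).  The binary symptomatic-vasospasm
outcome is drawn from a logistic model with planted, tunable per-feature
log-odds contributions, so the classifier's recoverable signal is known by
construction.

Marginal distributions are clinically plausible defaults (SAH skews female
and middle-aged; Fisher grades skew high in a cohort that bled; roughly
half the patients are ventilated); they are documented choices, not
estimates of any real cohort, and no covariance structure beyond the
planted outcome model is reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .records import PatientRecord, validate_record

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "implied_prevalence",
    "implied_bayes_accuracy",
    "worst_case_patient",
    "best_case_patient",
]

#: Centers subtracted from features before applying planted log-odds, so
#: the intercept stays interpretable as the baseline prevalence logit.
_EFFECT_CENTERS = {
    "fisher_grade": 3.0,
    "hh_grade": 2.5,
    "age": 55.0,
    "op_duration_min": 150.0,
    "treatment_surgical": 0.5,
}

#: Default planted log-odds per unit of each (centered) feature.  Fisher
#: grade carries the strongest association with vasospasm, Hunt & Hess the
#: next; age is mildly protective (vasospasm risk is highest in younger SAH
#: patients); long operations and surgical treatment add modest risk.
DEFAULT_EFFECTS: dict[str, float] = {
    "fisher_grade": 0.9,
    "hh_grade": 0.5,
    "age": -0.03,
    "op_duration_min": 0.004,
    "treatment_surgical": 0.4,
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``effects`` maps feature names to log-odds-per-unit contributions to
    the symptomatic-vasospasm outcome; ``baseline_prevalence`` is the
    outcome probability of a patient at every effect's center.
    """

    n_total: int = 87
    n_surgical: int = 45
    seed: int = 0
    baseline_prevalence: float = 0.30
    effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_surgical <= self.n_total:
            raise ValueError("n_surgical must lie in [0, n_total]")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie strictly in (0, 1)")
        unknown = set(self.effects) - set(_EFFECT_CENTERS)
        if unknown:
            raise ValueError(f"unknown effect features: {sorted(unknown)}")

    @property
    def n_endovascular(self) -> int:
        return self.n_total - self.n_surgical

    def to_yaml(self, path: Optional[str] = None) -> str:
        d = {
            "n_total": self.n_total,
            "n_surgical": self.n_surgical,
            "seed": self.seed,
            "baseline_prevalence": self.baseline_prevalence,
            "effects": dict(self.effects),
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "CohortSpec":
        if "\n" not in source and source.endswith((".yaml", ".yml")):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls(**data)

    def null(self) -> "CohortSpec":
        """The same spec with every planted effect removed."""
        return replace(self, effects={})


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Draw a labeled synthetic cohort table.

    Returns one row per patient with risk-model features, scoring-scale
    fields, the binary ``symptomatic_vasospasm`` outcome, and the planted
    outcome probability in ``true_risk`` (known only because the cohort is
    synthetic; drop it before any honest evaluation of a fitted model's
    calibration).  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total

    treatment = np.array(
        ["surgical"] * spec.n_surgical + ["endovascular"] * spec.n_endovascular
    )
    rng.shuffle(treatment)

    sex = rng.choice(["female", "male"], size=n, p=[0.65, 0.35])
    age = np.clip(np.rint(rng.normal(55, 12, n)), 18, 90).astype(int)
    hh_grade = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.20, 0.30, 0.25, 0.15, 0.10])
    fisher_grade = rng.choice([1, 2, 3, 4], size=n, p=[0.10, 0.20, 0.30, 0.40])
    bni_grade = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.15, 0.25, 0.30, 0.20, 0.10])
    com_hypertension = rng.random(n) < 0.45
    com_cardiovascular = rng.random(n) < 0.20
    com_pulmonary = rng.random(n) < 0.15
    anticoagulation = rng.choice(
        ["none", "ASA", "DOAC", "antiplatelet", "combination"],
        size=n,
        p=[0.70, 0.15, 0.07, 0.05, 0.03],
    )
    # Craniotomy with clipping runs longer than endovascular coiling.
    op_duration = np.where(
        treatment == "surgical",
        rng.lognormal(math.log(180), 0.30, n),
        rng.lognormal(math.log(120), 0.35, n),
    )
    op_duration = np.clip(op_duration, 30, 720).round(0)

    smoker = rng.random(n) < 0.40
    iaa_positive = rng.random(n) < 0.15
    iaa_pct = np.where(
        iaa_positive, 50 + 45 * rng.beta(1.5, 3.0, n), 45 * rng.beta(1.2, 4.0, n)
    ).round(1)
    bmi = np.clip(rng.normal(26.5, 4.5, n), 16.5, 45).round(1)
    egfr = np.clip(rng.normal(85, 25, n), 5, 140).round(0)
    ventilated = rng.random(n) < 0.55
    pf_ratio = np.where(ventilated, np.clip(rng.normal(230, 80, n), 45, 480).round(0), np.nan)
    peep = np.where(ventilated, np.clip(np.rint(rng.normal(8, 3, n)), 3, 20), np.nan)
    on_pressor = rng.random(n) < 0.60
    nad = np.where(on_pressor, np.minimum(rng.lognormal(math.log(0.5), 0.8, n), 8), 0.0).round(2)
    weight = np.clip(rng.normal(78, 15, n), 45, 140).round(1)

    logit = np.full(n, math.log(spec.baseline_prevalence / (1 - spec.baseline_prevalence)))
    feature_values = {
        "fisher_grade": fisher_grade.astype(float),
        "hh_grade": hh_grade.astype(float),
        "age": age.astype(float),
        "op_duration_min": op_duration,
        "treatment_surgical": (treatment == "surgical").astype(float),
    }
    for name, beta in spec.effects.items():
        logit = logit + beta * (feature_values[name] - _EFFECT_CENTERS[name])
    true_risk = _logistic(logit)
    outcome = (rng.random(n) < true_risk).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": [f"synth-{spec.seed}-{i:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "hh_grade": hh_grade,
            "fisher_grade": fisher_grade,
            "bni_grade": bni_grade,
            "com_hypertension": com_hypertension.astype(int),
            "com_cardiovascular": com_cardiovascular.astype(int),
            "com_pulmonary": com_pulmonary.astype(int),
            "anticoagulation": anticoagulation,
            "op_duration_min": op_duration,
            "treatment": treatment,
            "aneurysm_treatment": treatment,
            "smoker": smoker,
            "iaa_stenosis_pct": iaa_pct,
            "bmi": bmi,
            "egfr": egfr,
            "pf_ratio": pf_ratio,
            "peep": peep,
            "noradrenaline_mg_per_h": nad,
            "weight_kg": weight,
            "symptomatic_vasospasm": outcome,
            "true_risk": true_risk,
        }
    )
    return df


def implied_prevalence(cohort: pd.DataFrame) -> float:
    """Outcome prevalence implied by the planted probabilities."""
    return float(cohort["true_risk"].mean())


def implied_bayes_accuracy(cohort: pd.DataFrame) -> float:
    """Accuracy of the Bayes-optimal classifier on the planted model.

    The optimal rule predicts the outcome iff its planted probability
    exceeds 1/2, so its expected accuracy is the mean of
    ``max(p, 1 - p)`` over the cohort's planted probabilities.
    """
    p = cohort["true_risk"].to_numpy()
    return float(np.maximum(p, 1.0 - p).mean())


def worst_case_patient() -> PatientRecord:
    """A fixture record falling in the worst band of every parameter."""
    return validate_record(
        {
            "patient_id": "fixture-worst",
            "age": 70,
            "smoker": True,
            "iaa_stenosis_pct": 60.0,
            "bmi": 32.0,
            "egfr": 20.0,
            "pf_ratio": 80.0,
            "peep": 18.0,
            "noradrenaline_mg_per_h": 3.0,
            "ai_risk_prob": 0.9,
            "weight_kg": 80.0,
        }
    )


def best_case_patient() -> PatientRecord:
    """A fixture record at the floor of every parameter band."""
    return validate_record(
        {
            "patient_id": "fixture-best",
            "age": 40,
            "smoker": False,
            "iaa_stenosis_pct": 0.0,
            "bmi": 22.0,
            "egfr": 90.0,
            "noradrenaline_mg_per_h": 0.0,
            "ai_risk_prob": 0.2,
            "weight_kg": 70.0,
        }
    )
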