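"""Clinical record types shared by every part of the package.

A :class:`PatientRecord` is one patient's clinical snapshot at the moment a
treatment decision is being made: demographics, vascular status, body
habitus, renal function, ventilation burden, vasopressor requirement and the
machine-learning vasospasm-risk probability.  All downstream scoring
operates on validated records only, so every physical-range check lives
here.

Units are fixed by contract: age in whole years, stenosis in percent, BMI in
kg/m2, eGFR in mL/min, P/F ratio in mmHg, PEEP in cm H2O, noradrenaline in
mg/h, weight in kg.  No unit auto-detection is attempted.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Any, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "Treatment",
    "Parameter",
    "PatientRecord",
    "ParameterScore",
    "CostasResult",
    "RecordValidationError",
    "ScoringError",
    "validate_record",
]


class Treatment(str, Enum):
    """How the ruptured aneurysm was secured."""

    surgical = "surgical"
    endovascular = "endovascular"


class Parameter(str, Enum):
    """The nine scored parameters of the scale."""

    age = "age"
    smoking = "smoking"
    iaa = "iaa"
    bmi = "bmi"
    egfr = "egfr"
    pf_ratio = "pf_ratio"
    peep = "peep"
    noradrenaline = "noradrenaline"
    ai_risk = "ai_risk"


#: Maximum points each parameter can contribute.  Age, smoking and
#: intracranial atherosclerosis are binary criteria worth one point;
#: BMI, renal function and the AI risk band top out at two; the
#: ventilation metrics and noradrenaline requirement at three.
MAX_POINTS: dict[Parameter, int] = {
    Parameter.age: 1,
    Parameter.smoking: 1,
    Parameter.iaa: 1,
    Parameter.bmi: 2,
    Parameter.egfr: 2,
    Parameter.pf_ratio: 3,
    Parameter.peep: 3,
    Parameter.noradrenaline: 3,
    Parameter.ai_risk: 2,
}

TOTAL_MAX = sum(MAX_POINTS.values())  # 18


class RecordValidationError(ValueError):
    """Raised when raw patient input fails validation; names the fields."""

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        msg = "; ".join(f"{field}: {reason}" for field, reason in errors)
        super().__init__(f"invalid patient record: {msg}")


class ScoringError(ValueError):
    """Raised when a record lacks a field required to score a parameter."""

    def __init__(self, parameter: Parameter, reason: str):
        self.parameter = parameter
        super().__init__(f"cannot score {parameter.value}: {reason}")


class PatientRecord(BaseModel):
    """One patient's validated clinical snapshot.

    Ventilation fields (``pf_ratio``, ``peep``) must be supplied together;
    both absent means the patient is breathing spontaneously and the
    ventilation parameters score zero.  Intracranial arterial
    atherosclerosis (IAA) is accepted either as a stenosis percentage or as
    a pre-adjudicated boolean, because >=50% stenosis may be established by
    modalities (TCD, intraoperative inspection) that yield no percentage.
    BMI may be given directly or derived from height and weight.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    patient_id: str
    age: int = Field(ge=0, le=130, description="age in whole years")
    smoker: bool
    iaa_stenosis_pct: Optional[float] = Field(default=None, ge=0.0, le=100.0)
    iaa_detected: Optional[bool] = None
    bmi: Optional[float] = Field(default=None, gt=0.0, lt=120.0)
    height_m: Optional[float] = Field(default=None, gt=0.3, lt=2.8)
    weight_kg: Optional[float] = Field(default=None, gt=0.0, lt=400.0)
    egfr: float = Field(ge=0.0, le=300.0, description="estimated GFR, mL/min")
    pf_ratio: Optional[float] = Field(default=None, gt=0.0, le=700.0)
    peep: Optional[float] = Field(default=None, ge=0.0, le=50.0)
    noradrenaline_mg_per_h: float = Field(ge=0.0, le=50.0)
    ai_risk_prob: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    aneurysm_treatment: Optional[Treatment] = None

    @field_validator("age", mode="before")
    @classmethod
    def _floor_fractional_age(cls, v: Any) -> Any:
        # Ages are whole years; a fractional age is floored (clinical
        # convention: you are 64 until your 65th birthday).
        if isinstance(v, float) and math.isfinite(v):
            return math.floor(v)
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "PatientRecord":
        if self.bmi is None:
            if self.height_m is not None and self.weight_kg is not None:
                object.__setattr__(self, "bmi", self.weight_kg / self.height_m**2)
            else:
                raise ValueError("bmi missing and not derivable (need height_m and weight_kg)")
        if (self.pf_ratio is None) != (self.peep is None):
            raise ValueError("pf_ratio and peep must be supplied together or both omitted")
        if self.iaa_stenosis_pct is None and self.iaa_detected is None:
            raise ValueError("one of iaa_stenosis_pct or iaa_detected is required")
        return self

    @property
    def ventilated(self) -> bool:
        """Whether the patient is mechanically ventilated."""
        return self.pf_ratio is not None

    @property
    def iaa_positive(self) -> bool:
        """Adjudicated intracranial atherosclerosis >=50% stenosis."""
        if self.iaa_stenosis_pct is not None:
            return self.iaa_stenosis_pct >= 50.0
        return bool(self.iaa_detected)


class ParameterScore(BaseModel):
    """Points awarded for a single parameter, with its band label."""

    model_config = ConfigDict(frozen=True)

    parameter: Parameter
    points: int = Field(ge=0, le=3)
    category_label: str
    flags: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _within_parameter_range(self) -> "ParameterScore":
        cap = MAX_POINTS[self.parameter]
        if self.points > cap:
            raise ValueError(f"{self.parameter.value} points {self.points} exceed maximum {cap}")
        return self


class CostasResult(BaseModel):
    """The aggregate score: nine parameter scores summing to 0-18."""

    patient_id: str
    parameter_scores: tuple[ParameterScore, ...]
    total: int = Field(ge=0, le=TOTAL_MAX)
    flags: tuple[str, ...] = ()
    table_version: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "CostasResult":
        if len(self.parameter_scores) != len(Parameter):
            raise ValueError("expected one score per parameter")
        seen = {s.parameter for s in self.parameter_scores}
        if seen != set(Parameter):
            raise ValueError("parameter scores must cover all nine parameters exactly once")
        if self.total != sum(s.points for s in self.parameter_scores):
            raise ValueError("total does not equal the sum of parameter points")
        return self

    def score_for(self, parameter: Parameter) -> ParameterScore:
        return next(s for s in self.parameter_scores if s.parameter == parameter)


def validate_record(raw: Mapping[str, Any]) -> PatientRecord:
    """Validate a raw field mapping into a :class:`PatientRecord`.

    Raises :class:`RecordValidationError` naming each offending field.
    Blank / NaN values are treated as absent so CSV rows with empty cells
    validate naturally.
    """
    cleaned: dict[str, Any] = {}
    for key, value in raw.items():
        if value is None:
            continue
        if isinstance(value, float) and math.isnan(value):
            continue
        if isinstance(value, str) and value.strip() == "":
            continue
        cleaned[key] = value
    try:
        return PatientRecord(**cleaned)
    except ValidationError as exc:
        errors = [
            (".".join(str(loc) for loc in e["loc"]) or "record", e["msg"])
            for e in exc.errors()
        ]
        raise RecordValidationError(errors) from exc
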