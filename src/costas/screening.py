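"""Rule-based screening for the events that trigger scoring.

Two detectors:

* :func:`suspect_cvs` - suspected symptomatic cerebral vasospasm from
  transcranial Doppler: mean flow velocity above 190 cm/s, or a rise of at
  least 50% over the previous measurement of the same vessel.
* :func:`dci_deterioration` - clinical deterioration attributable to
  delayed cerebral ischemia: a newly present focal deficit (hemiparesis,
  aphasia, apraxia, hemianopsia, neglect) or a Glasgow Coma Scale drop of
  at least 2 points (on the total, or on any single component - eye,
  verbal, motor on either side), lasting at least one hour and not
  explained by another cause.

Attribution to other causes (CT/MRI, laboratory work-up) is a clinical
adjudication supplied as an input flag, never computed here.  Both rules
are pure functions of their inputs.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "TcdObservation",
    "NeuroObservation",
    "ScreeningResult",
    "FOCAL_DEFICITS",
    "suspect_cvs",
    "dci_deterioration",
]

#: Absolute TCD velocity threshold, cm/s (strict: exactly 190 does not trigger).
TCD_ABSOLUTE_CM_S = 190.0
#: Relative velocity rise threshold (inclusive at exactly 50%).
TCD_RELATIVE_RISE = 0.5
#: Minimum duration of deterioration, hours.
DCI_MIN_DURATION_H = 1.0
#: GCS drop threshold (total or single component).
GCS_DROP = 2

FOCAL_DEFICITS = ("hemiparesis", "aphasia", "apraxia", "hemianopsia", "neglect")


class TcdObservation(BaseModel):
    """One transcranial Doppler measurement of a named vessel."""

    model_config = ConfigDict(frozen=True)

    timestamp: str
    vessel: str
    mean_velocity_cm_s: float = Field(ge=0.0)


class NeuroObservation(BaseModel):
    """A timestamped neurological examination.

    GCS components: eye 1-4, verbal 1-5, motor 1-6 on either side; the
    total uses the better motor response, so it spans 3-15.
    """

    model_config = ConfigDict(frozen=True)

    timestamp: str
    gcs_eye: int = Field(ge=1, le=4)
    gcs_verbal: int = Field(ge=1, le=5)
    gcs_motor_left: int = Field(ge=1, le=6)
    gcs_motor_right: int = Field(ge=1, le=6)
    hemiparesis: bool = False
    aphasia: bool = False
    apraxia: bool = False
    hemianopsia: bool = False
    neglect: bool = False
    duration_h: float = Field(default=0.0, ge=0.0)
    other_cause: bool = False

    @property
    def gcs_total(self) -> int:
        total = self.gcs_eye + self.gcs_verbal + max(self.gcs_motor_left, self.gcs_motor_right)
        assert 3 <= total <= 15
        return total

    def deficits(self) -> frozenset[str]:
        return frozenset(d for d in FOCAL_DEFICITS if getattr(self, d))


class ScreeningResult(BaseModel):
    """Outcome of a screening rule: triggered or not, and why."""

    model_config = ConfigDict(frozen=True)

    triggered: bool
    reasons: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _reason_iff_triggered(self) -> "ScreeningResult":
        if self.triggered and not self.reasons:
            raise ValueError("a triggered result must state a reason")
        return self

    def __bool__(self) -> bool:
        return self.triggered


def suspect_cvs(
    current: TcdObservation, previous: Optional[TcdObservation] = None
) -> ScreeningResult:
    """Flag suspected cerebral vasospasm from TCD velocities.

    Triggers on velocity > 190 cm/s, or on a rise of >= 50% relative to the
    previous measurement of the same vessel.  A previous velocity of zero
    makes the relative rule undefined; the absolute rule is evaluated
    first, and if it too is silent an error is raised.
    """
    reasons: list[str] = []
    v = current.mean_velocity_cm_s
    if v > TCD_ABSOLUTE_CM_S:
        reasons.append(f"absolute: {v:g} cm/s > {TCD_ABSOLUTE_CM_S:g} cm/s")
    if previous is not None:
        if previous.vessel != current.vessel:
            raise ValueError(
                f"relative rule needs the same vessel: {previous.vessel!r} vs {current.vessel!r}"
            )
        if previous.mean_velocity_cm_s == 0:
            if not reasons:
                raise ValueError("previous velocity is 0: relative rise undefined")
        else:
            rise = (v - previous.mean_velocity_cm_s) / previous.mean_velocity_cm_s
            if rise >= TCD_RELATIVE_RISE:
                reasons.append(f"relative: rise of {rise:.0%} >= {TCD_RELATIVE_RISE:.0%}")
    return ScreeningResult(triggered=bool(reasons), reasons=tuple(reasons))


def dci_deterioration(
    baseline: NeuroObservation, current: NeuroObservation
) -> ScreeningResult:
    """Flag clinical deterioration attributable to delayed cerebral ischemia."""
    candidates: list[str] = []
    new_deficits = current.deficits() - baseline.deficits()
    for d in sorted(new_deficits):
        candidates.append(f"new focal deficit: {d}")
    total_drop = baseline.gcs_total - current.gcs_total
    if total_drop >= GCS_DROP:
        candidates.append(f"GCS total drop of {total_drop}")
    for comp in ("gcs_eye", "gcs_verbal", "gcs_motor_left", "gcs_motor_right"):
        drop = getattr(baseline, comp) - getattr(current, comp)
        if drop >= GCS_DROP:
            candidates.append(f"{comp} drop of {drop}")
    if not candidates:
        return ScreeningResult(triggered=False)
    if current.duration_h < DCI_MIN_DURATION_H:
        return ScreeningResult(triggered=False)
    if current.other_cause:
        return ScreeningResult(triggered=False)
    return ScreeningResult(triggered=True, reasons=tuple(candidates))
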