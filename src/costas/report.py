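"""Human- and machine-readable triage reports."""

from __future__ import annotations

import json
from typing import Any, Mapping, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .records import CostasResult, Parameter, ParameterScore

__all__ = ["TriageReport", "render_report", "parse_report"]


class TriageReport(BaseModel):
    """One patient's triage summary around the aggregate score."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    result: CostasResult
    screening: Optional[dict] = None
    dosing: Optional[dict] = None
    risk_prob: Optional[float] = None
    scale_version: str
    timestamp: Optional[str] = None

    @model_validator(mode="after")
    def _consistent(self) -> "TriageReport":
        if self.result.patient_id != self.patient_id:
            raise ValueError("report patient_id does not match its result")
        return self

    def to_json(self) -> str:
        """Deterministic JSON rendering (stable key order)."""
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=2)

    def to_text(self) -> str:
        """Fixed-width console rendering."""
        lines = [
            f"COSTAS triage report - patient {self.patient_id}",
            f"scale version: {self.scale_version}"
            + (f"  ({self.timestamp})" if self.timestamp else ""),
            "-" * 58,
        ]
        for s in self.result.parameter_scores:
            flag_txt = f"  [{', '.join(s.flags)}]" if s.flags else ""
            lines.append(
                f"{s.parameter.value:<14} {s.category_label:<28} {s.points} pt{flag_txt}"
            )
        lines.append("-" * 58)
        lines.append(f"{'TOTAL':<14} {'':<28} {self.result.total} / 18")
        if self.risk_prob is not None:
            lines.append(f"model vasospasm probability: {self.risk_prob:.3f}")
        if self.screening is not None:
            lines.append(f"screening: {json.dumps(self.screening, sort_keys=True)}")
        if self.dosing is not None:
            lines.append(f"dosing: {json.dumps(self.dosing, sort_keys=True)}")
        return "\n".join(lines) + "\n"


def render_report(
    result: CostasResult,
    screening: Optional[Mapping[str, Any]] = None,
    dosing: Optional[Mapping[str, Any]] = None,
    risk_prob: Optional[float] = None,
    timestamp: Optional[str] = None,
) -> TriageReport:
    """Assemble a :class:`TriageReport` around a scoring result."""
    return TriageReport(
        patient_id=result.patient_id,
        result=result,
        screening=dict(screening) if screening is not None else None,
        dosing=dict(dosing) if dosing is not None else None,
        risk_prob=risk_prob,
        scale_version=result.table_version,
        timestamp=timestamp,
    )


def parse_report(text: str) -> TriageReport:
    """Reconstruct a report (and its :class:`CostasResult`) from JSON."""
    data = json.loads(text)
    data["result"]["parameter_scores"] = tuple(
        ParameterScore(
            parameter=Parameter(s["parameter"]),
            points=s["points"],
            category_label=s["category_label"],
            flags=tuple(s.get("flags", ())),
        )
        for s in data["result"]["parameter_scores"]
    )
    data["result"] = CostasResult(**data["result"])
    return TriageReport(**data)
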