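"""Per-parameter scorers and the 0-18 aggregate.

Nine parameters are scored: three binary criteria (age >=65, cigarette
smoking, intracranial atherosclerosis >=50% stenosis, one point each), body
habitus (BMI, 0-2), renal function (eGFR, 0-2), two ventilation metrics
(P/F ratio and PEEP, 0-3 each), the noradrenaline requirement (0-3) and the
machine-learning vasospasm-risk probability (0-2).  The total is their sum,
0 to 18; higher means a sicker patient with more to gain - and more to lose
- from invasive intra-arterial spasmolysis.  No treat/no-treat cut-off is
defined on the total; the scale is a triage summary, not a decision rule.

The module offers both plain functions (``score_age`` ... ``total_score``)
and :class:`CostasScorer`, a stateless scikit-learn transformer that scores
a whole patient table at once.
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import (
    CostasResult,
    Parameter,
    ParameterScore,
    PatientRecord,
    ScoringError,
)
from .tables import PEEP_PRINTED_MAX, ScoringTable, default_table

__all__ = [
    "score_age",
    "score_smoking",
    "score_iaa",
    "score_bmi",
    "score_gfr",
    "score_pf_ratio",
    "score_peep",
    "score_noradrenaline",
    "score_ai_risk",
    "total_score",
    "CostasScorer",
]


def _table(table: Optional[ScoringTable]) -> ScoringTable:
    return table if table is not None else default_table()


def score_age(age: float, table: Optional[ScoringTable] = None) -> ParameterScore:
    """One point for age >= 65 years (geriatric threshold)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return _table(table).score(Parameter.age, float(age))


def score_smoking(smoker: bool, table: Optional[ScoringTable] = None) -> ParameterScore:
    """One point for cigarette smoking."""
    return _table(table).score(Parameter.smoking, 1.0 if smoker else 0.0)


def score_iaa(
    stenosis: Union[float, bool], table: Optional[ScoringTable] = None
) -> ParameterScore:
    """One point for intracranial arterial atherosclerosis >=50% stenosis.

    Accepts either the stenosis percentage of the worst intracranial vessel
    or a pre-adjudicated boolean (for modalities with no percentage).
    """
    if isinstance(stenosis, bool):
        value = 50.0 if stenosis else 0.0
    else:
        if not 0 <= stenosis <= 100:
            raise ValueError("stenosis percent must be in [0, 100]")
        value = float(stenosis)
    return _table(table).score(Parameter.iaa, value)


def score_bmi(bmi: float, table: Optional[ScoringTable] = None) -> ParameterScore:
    """0/1/2 points for normal weight / overweight / obesity."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return _table(table).score(Parameter.bmi, float(bmi))


def score_gfr(egfr: float, table: Optional[ScoringTable] = None) -> ParameterScore:
    """0/1/2 points for KDOQI low / moderate / high renal risk."""
    if egfr < 0:
        raise ValueError("egfr must be non-negative")
    return _table(table).score(Parameter.egfr, float(egfr))


def _not_ventilated(parameter: Parameter) -> ParameterScore:
    return ParameterScore(
        parameter=parameter, points=0, category_label="not ventilated", flags=()
    )


def score_pf_ratio(
    pf: Optional[float], ventilated: bool = True, table: Optional[ScoringTable] = None
) -> ParameterScore:
    """1/2/3 points for mild/moderate/severe Berlin oxygenation impairment.

    A spontaneously breathing patient has no ventilation burden and scores
    zero.
    """
    if not ventilated or pf is None:
        return _not_ventilated(Parameter.pf_ratio)
    if pf <= 0:
        raise ValueError("pf_ratio must be positive when ventilated")
    return _table(table).score(Parameter.pf_ratio, float(pf))


def score_peep(
    peep: Optional[float], ventilated: bool = True, table: Optional[ScoringTable] = None
) -> ParameterScore:
    """1/2/3 points for mild/moderate/severe PEEP requirement."""
    if not ventilated or peep is None:
        return _not_ventilated(Parameter.peep)
    if peep < 0:
        raise ValueError("peep must be non-negative")
    extra = ("peep_above_band",) if peep > PEEP_PRINTED_MAX else ()
    return _table(table).score(Parameter.peep, float(peep), extra_flags=extra)


def score_noradrenaline(
    dose_mg_per_h: float, table: Optional[ScoringTable] = None
) -> ParameterScore:
    """0-3 points by institutional mg/h noradrenaline bands."""
    if dose_mg_per_h < 0:
        raise ValueError("noradrenaline dose must be non-negative")
    return _table(table).score(Parameter.noradrenaline, float(dose_mg_per_h))


def score_ai_risk(prob: float, table: Optional[ScoringTable] = None) -> ParameterScore:
    """0/1/2 points for the model's predicted vasospasm probability."""
    if not 0 <= prob <= 1:
        raise ValueError("ai_risk_prob must be in [0, 1]")
    return _table(table).score(Parameter.ai_risk, float(prob))


def total_score(
    record: PatientRecord,
    table: Optional[ScoringTable] = None,
    ai_risk_prob: Optional[float] = None,
) -> CostasResult:
    """Score all nine parameters and aggregate to the 0-18 total.

    ``ai_risk_prob`` overrides the record's stored probability, e.g. when
    it has just been computed by the risk model.
    """
    tab = _table(table)
    prob = ai_risk_prob if ai_risk_prob is not None else record.ai_risk_prob
    if prob is None:
        raise ScoringError(Parameter.ai_risk, "no AI risk probability on record and none supplied")
    scores = (
        score_age(record.age, tab),
        score_smoking(record.smoker, tab),
        score_iaa(
            record.iaa_stenosis_pct
            if record.iaa_stenosis_pct is not None
            else bool(record.iaa_detected),
            tab,
        ),
        score_bmi(record.bmi, tab),
        score_gfr(record.egfr, tab),
        score_pf_ratio(record.pf_ratio, record.ventilated, tab),
        score_peep(record.peep, record.ventilated, tab),
        score_noradrenaline(record.noradrenaline_mg_per_h, tab),
        score_ai_risk(prob, tab),
    )
    flags = tuple(f for s in scores for f in s.flags)
    return CostasResult(
        patient_id=record.patient_id,
        parameter_scores=scores,
        total=sum(s.points for s in scores),
        flags=flags,
        table_version=tab.version,
    )


class CostasScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer scoring a patient table row-wise.

    The transformer is stateless (the scale is fixed clinical knowledge,
    not fitted from data); ``fit`` only resolves and validates the scoring
    table so the estimator composes with pipelines and ``get_params`` /
    ``set_params`` grid search over alternative tables.

    Parameters
    ----------
    table : ScoringTable, optional
        Scoring bands to apply; the shipped default when omitted.

    Attributes
    ----------
    table_ : ScoringTable
        The resolved table after ``fit``.
    """

    def __init__(self, table: Optional[ScoringTable] = None):
        self.table = table

    def fit(self, X=None, y=None) -> "CostasScorer":
        self.table_ = _table(self.table)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score each row; returns per-parameter points, total and flags."""
        if not hasattr(self, "table_"):
            self.fit()
        from .records import validate_record  # local to keep import light

        rows = []
        for _, row in X.iterrows():
            record = validate_record(row.to_dict())
            result = total_score(record, self.table_)
            out = {"patient_id": record.patient_id}
            for s in result.parameter_scores:
                out[f"{s.parameter.value}_points"] = s.points
            out["total"] = result.total
            out["flags"] = ";".join(result.flags)
            rows.append(out)
        return pd.DataFrame(rows)

    def score_record(self, record: PatientRecord) -> CostasResult:
        if not hasattr(self, "table_"):
            self.fit()
        return total_score(record, self.table_)
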