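"""Per-parameter band scoring and the 0-18 aggregate.

The oracle used throughout is a literal transcription of the published
cut-offs as comparison chains, written independently of the interval-band
machinery in ``costas.tables``.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costas.records import MAX_POINTS, Parameter, ScoringError
from costas.scoring import (
    CostasScorer,
    score_age,
    score_ai_risk,
    score_bmi,
    score_gfr,
    score_iaa,
    score_noradrenaline,
    score_peep,
    score_pf_ratio,
    score_smoking,
    total_score,
)
from costas.tables import ScoringTable

from .conftest import make_record, random_records

# -- independent oracle: literal threshold chains ----------------------


def oracle_age(age):
    return 1 if age >= 65 else 0


def oracle_iaa(pct):
    return 1 if pct >= 50 else 0


def oracle_bmi(bmi):
    if bmi >= 30:
        return 2
    if bmi >= 25:
        return 1
    return 0  # normal weight, and underweight below 18.5


def oracle_gfr(egfr):
    if egfr < 30:
        return 2
    if egfr < 45:
        return 1
    return 0


def oracle_pf(pf):
    if pf <= 100:
        return 3
    if pf <= 200:
        return 2
    if pf <= 300:
        return 1
    return 0


def oracle_peep(peep):
    if peep >= 15:
        return 3
    if peep >= 10:
        return 2
    if peep >= 5:
        return 1
    return 0


def oracle_nad(dose):
    if dose == 0:
        return 0
    if dose <= 0.5:
        return 1
    if dose < 2:
        return 2
    return 3


def oracle_ai(prob):
    if prob >= 0.75:
        return 2
    if prob > 0.5:
        return 1
    return 0


ORACLES = {
    Parameter.age: oracle_age,
    Parameter.iaa: oracle_iaa,
    Parameter.bmi: oracle_bmi,
    Parameter.egfr: oracle_gfr,
    Parameter.pf_ratio: oracle_pf,
    Parameter.peep: oracle_peep,
    Parameter.noradrenaline: oracle_nad,
    Parameter.ai_risk: oracle_ai,
}

SCORERS = {
    Parameter.age: score_age,
    Parameter.iaa: score_iaa,
    Parameter.bmi: score_bmi,
    Parameter.egfr: score_gfr,
    Parameter.pf_ratio: score_pf_ratio,
    Parameter.peep: score_peep,
    Parameter.noradrenaline: score_noradrenaline,
    Parameter.ai_risk: score_ai_risk,
}

GRID_RANGES = {
    Parameter.age: (0, 110),
    Parameter.iaa: (0, 100),
    Parameter.bmi: (10, 60),
    Parameter.egfr: (0, 150),
    Parameter.pf_ratio: (1, 500),
    Parameter.peep: (0, 30),
    Parameter.noradrenaline: (0, 8),
    Parameter.ai_risk: (0, 1),
}


# -- published band midpoints and edges --------------------------------


@pytest.mark.parametrize(
    "scorer, value, points, label",
    [
        (score_age, 65, 1, ">=65 years"),
        (score_age, 64, 0, "<65 years"),
        (score_age, 20, 0, "<65 years"),
        (score_iaa, 50.0, 1, ">=50% stenosis"),
        (score_iaa, 49.0, 0, "<50% stenosis"),
        (score_bmi, 22.0, 0, "normal weight"),
        (score_bmi, 27.0, 1, "overweight"),
        (score_bmi, 30.0, 2, "obesity"),
        (score_bmi, 32.0, 2, "obesity"),
        (score_gfr, 50.0, 0, "low risk"),
        (score_gfr, 35.0, 1, "moderate risk"),
        (score_gfr, 20.0, 2, "high risk"),
        (score_pf_ratio, 250.0, 1, "mild"),
        (score_pf_ratio, 150.0, 2, "moderate"),
        (score_pf_ratio, 80.0, 3, "severe"),
        (score_pf_ratio, 100.0, 3, "severe"),  # gap closed conservatively
        (score_pf_ratio, 400.0, 0, "no ventilation impairment"),
        (score_peep, 7.0, 1, "mild"),
        (score_peep, 12.0, 2, "moderate"),
        (score_peep, 18.0, 3, "severe"),
        (score_peep, 3.0, 0, "minimal"),
        (score_noradrenaline, 0.0, 0, "no noradrenaline"),
        (score_noradrenaline, 0.3, 1, "low risk"),
        (score_noradrenaline, 0.5, 1, "low risk"),
        (score_noradrenaline, 1.0, 2, "moderate risk"),
        (score_noradrenaline, 2.0, 3, "high risk"),
        (score_noradrenaline, 2.5, 3, "high risk"),
        (score_ai_risk, 0.4, 0, "low risk"),
        (score_ai_risk, 0.5, 0, "low risk"),
        (score_ai_risk, 0.6, 1, "moderate risk"),
        (score_ai_risk, 0.75, 2, "high risk"),
        (score_ai_risk, 0.8, 2, "high risk"),
    ],
)
def test_published_bands(scorer, value, points, label):
    s = scorer(value)
    assert s.points == points
    assert s.category_label == label


def test_smoking_points_and_label():
    assert score_smoking(True).points == 1
    assert score_smoking(True).category_label == "smoker"
    assert score_smoking(False).points == 0


def test_iaa_accepts_adjudicated_boolean():
    assert score_iaa(True).points == 1
    assert score_iaa(False).points == 0


def test_out_of_band_values_flagged_not_scored():
    under = score_bmi(17.0)
    assert under.points == 0 and "underweight_unspecified" in under.flags
    good_kidney = score_gfr(90.0)
    assert good_kidney.points == 0 and "above_kdoqi_bands" in good_kidney.flags
    high_peep = score_peep(22.0)
    assert high_peep.points == 3 and "peep_above_band" in high_peep.flags


def test_unventilated_patient_scores_zero_on_ventilation_metrics():
    assert score_pf_ratio(None, ventilated=False).points == 0
    assert score_peep(None, ventilated=False).points == 0


# -- dense-grid agreement with the literal oracle ----------------------


def test_banded_scorers_match_literal_oracle_on_dense_grid():
    """~1.2e5 grid points per run: every scorer agrees with the oracle."""
    n = 15000
    for param, oracle in ORACLES.items():
        lo, hi = GRID_RANGES[param]
        step = (hi - lo) / n
        scorer = SCORERS[param]
        for i in range(n + 1):
            x = lo + i * step
            if param is Parameter.age:
                x = int(x)
            got = scorer(x).points
            assert got == oracle(x), f"{param.value} at {x}"


def test_band_edges_exactly():
    """The contested edges land on the documented side."""
    edge_cases = [
        (score_bmi, 18.5, 0),
        (score_bmi, 25.0, 1),
        (score_gfr, 30.0, 1),
        (score_gfr, 45.0, 0),
        (score_gfr, 60.0, 0),
        (score_pf_ratio, 200.0, 2),
        (score_pf_ratio, 300.0, 1),
        (score_peep, 5.0, 1),
        (score_peep, 10.0, 2),
        (score_peep, 15.0, 3),
        (score_noradrenaline, 1.9, 2),
        (score_ai_risk, 0.5 + 1e-12, 1),
    ]
    for scorer, value, expected in edge_cases:
        assert scorer(value).points == expected, f"{scorer.__name__}({value})"


# -- aggregate ---------------------------------------------------------


def test_worst_case_totals_eighteen(worst_record):
    assert total_score(worst_record).total == 18


def test_best_case_totals_zero(best_record):
    assert total_score(best_record).total == 0


def test_hand_summed_mixed_record():
    rec = make_record(
        age=70,
        smoker=True,
        iaa_stenosis_pct=0.0,
        bmi=28.0,
        egfr=50.0,
        pf_ratio=250.0,
        peep=8.0,
        noradrenaline_mg_per_h=1.0,
        ai_risk_prob=0.60,
    )
    # 1 + 1 + 0 + 1 + 0 + 1 + 1 + 2 + 1
    assert total_score(rec).total == 8


def test_total_conserves_component_sum_and_range():
    for rec in random_records(300, seed=11):
        res = total_score(rec)
        assert res.total == sum(s.points for s in res.parameter_scores)
        assert 0 <= res.total <= 18


def test_missing_ai_probability_names_the_parameter():
    rec = make_record()
    object.__setattr__(rec, "ai_risk_prob", None)
    with pytest.raises(ScoringError, match="ai_risk"):
        total_score(rec)
    assert total_score(rec, ai_risk_prob=0.9).score_for(Parameter.ai_risk).points == 2


def test_per_parameter_maxima_sum_to_eighteen(table):
    maxima = [table.max_points(p) for p in Parameter]
    assert maxima == [1, 1, 1, 2, 2, 3, 3, 3, 2]
    assert sum(maxima) == 18
    assert table.total_max == 18
    assert {p: table.max_points(p) for p in Parameter} == MAX_POINTS


# -- monotonicity: worsening one parameter never lowers the total ------


WORSENING_GRIDS = {
    "age": [20, 40, 64, 65, 70, 90],
    "noradrenaline_mg_per_h": [0, 0.2, 0.5, 0.7, 1.9, 2.0, 4.0],
    "peep": [0, 4, 5, 9, 10, 14, 15, 22],
    "ai_risk_prob": [0, 0.5, 0.51, 0.74, 0.75, 1.0],
    "iaa_stenosis_pct": [0, 30, 49, 50, 80, 100],
    "bmi": [18.5, 22, 25, 29, 30, 45],  # above the underweight gap
    "pf_ratio": [480, 300, 250, 200, 150, 100, 60],  # lower is worse
    "egfr": [120, 60, 59, 45, 44, 30, 29, 5],  # lower is worse
}


@pytest.mark.parametrize("field, grid", sorted(WORSENING_GRIDS.items()))
def test_total_monotone_in_each_parameter(field, grid):
    totals = []
    for value in grid:
        kwargs = {field: value}
        if field in ("pf_ratio", "peep"):
            kwargs.setdefault("pf_ratio", 250.0)
            kwargs.setdefault("peep", 5.0)
            kwargs[field] = value
        totals.append(total_score(make_record(**kwargs)).total)
    assert totals == sorted(totals), f"{field}: {totals}"


def test_ventilation_onset_never_lowers_total():
    base = total_score(make_record()).total
    vented = total_score(make_record(pf_ratio=250.0, peep=8.0)).total
    assert vented >= base


# -- property tests over randomized records ----------------------------


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    age=st.integers(0, 110),
    smoker=st.booleans(),
    iaa=st.floats(0, 100),
    bmi=st.floats(12, 60),
    egfr=st.floats(0, 150),
    vent=st.booleans(),
    pf=st.floats(40, 500),
    peep=st.floats(0, 28),
    nad=st.floats(0, 8),
    ai=st.floats(0, 1),
)
def test_every_valid_record_scores_in_range(age, smoker, iaa, bmi, egfr, vent, pf, peep, nad, ai):
    kwargs = dict(
        age=age,
        smoker=smoker,
        iaa_stenosis_pct=iaa,
        bmi=bmi,
        egfr=egfr,
        noradrenaline_mg_per_h=nad,
        ai_risk_prob=ai,
    )
    if vent:
        kwargs.update(pf_ratio=pf, peep=peep)
    res = total_score(make_record(**kwargs))
    assert 0 <= res.total <= 18
    for s in res.parameter_scores:
        assert 0 <= s.points <= MAX_POINTS[s.parameter]


# -- table structure and serialization ---------------------------------


def test_table_yaml_round_trip(table):
    clone = ScoringTable.from_yaml(table.to_yaml())
    assert clone.to_dict() == table.to_dict()
    for param, oracle in ORACLES.items():
        lo, hi = GRID_RANGES[param]
        for frac in (0.0, 0.21, 0.5, 0.83, 1.0):
            x = lo + frac * (hi - lo)
            if x == 0 and param in (Parameter.bmi, Parameter.pf_ratio):
                continue
            assert clone.score(param, x).points == oracle(x)


def test_overlapping_or_gapped_tables_rejected(table):
    from costas.tables import Band

    bad = dict(table.bands)
    bad[Parameter.age] = (Band(0, 65, 0, "a"), Band(66, math.inf, 1, "b"))
    with pytest.raises(ValueError, match="gap or overlap"):
        ScoringTable(bands=bad)
    bad[Parameter.age] = (
        Band(0, 65, 0, "a", upper_closed=True),
        Band(65, math.inf, 1, "b"),
    )
    with pytest.raises(ValueError, match="edge"):
        ScoringTable(bands=bad)


# -- sklearn transformer surface ---------------------------------------


def test_costas_scorer_transforms_a_patient_table():
    import pandas as pd

    records = list(random_records(25, seed=5))
    frame = pd.DataFrame([r.model_dump(mode="json") for r in records])
    scorer = CostasScorer().fit()
    out = scorer.transform(frame)
    assert len(out) == 25
    expected = [total_score(r).total for r in records]
    assert out["total"].tolist() == expected
    assert scorer.get_params() == {"table": None}
    cloned = CostasScorer(**scorer.get_params())
    assert cloned.fit().transform(frame)["total"].tolist() == expected
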