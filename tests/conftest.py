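import numpy as np
import pytest

from costas.cohort import best_case_patient, worst_case_patient
from costas.records import validate_record
from costas.tables import default_table


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture
def worst_record():
    return worst_case_patient()


@pytest.fixture
def best_record():
    return best_case_patient()


def make_record(**overrides):
    """A plain mid-range valid record, fields overridable per test."""
    base = {
        "patient_id": "t-0",
        "age": 50,
        "smoker": False,
        "iaa_stenosis_pct": 10.0,
        "bmi": 23.0,
        "egfr": 80.0,
        "noradrenaline_mg_per_h": 0.0,
        "ai_risk_prob": 0.2,
        "weight_kg": 75.0,
    }
    base.update(overrides)
    return validate_record(base)


def random_records(n, seed):
    """Physically valid records spanning every band, drawn uniformly."""
    rng = np.random.default_rng(seed)
    ventilated = rng.random(n) < 0.5
    for i in range(n):
        raw = {
            "patient_id": f"r-{i}",
            "age": int(rng.integers(0, 101)),
            "smoker": bool(rng.random() < 0.5),
            "iaa_stenosis_pct": float(rng.uniform(0, 100)),
            "bmi": float(rng.uniform(12, 50)),
            "egfr": float(rng.uniform(0, 140)),
            "noradrenaline_mg_per_h": float(rng.choice([0.0, rng.uniform(0, 6)])),
            "ai_risk_prob": float(rng.uniform(0, 1)),
            "weight_kg": float(rng.uniform(45, 140)),
        }
        if ventilated[i]:
            raw["pf_ratio"] = float(rng.uniform(40, 500))
            raw["peep"] = float(rng.uniform(0, 25))
        yield validate_record(raw)
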