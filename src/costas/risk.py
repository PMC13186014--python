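"""Machine-learning vasospasm-risk prediction.

A kernel support-vector classifier estimates each patient's probability of
developing symptomatic cerebral vasospasm from admission-time features: sex,
age, Hunt & Hess grade, Fisher grade, BNI grade, comorbidities, prior
anticoagulation/antiplatelet therapy, operation or intervention duration and
the treatment modality.  The predicted probability feeds the AI-risk band
of the scoring scale.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``predict_proba``, ``get_params``) and evaluates itself the way the
original model was evaluated: a stratified holdout split plus k-fold
cross-validation, both reported as fitted attributes.  The kernel, its
hyperparameters, the holdout fraction and the fold count are configuration;
defaults are an RBF kernel with the median-distance bandwidth heuristic
(``gamma="scale"``), a 25% holdout and 5 folds.  Probabilities come from
Platt scaling (sigmoid calibration of the SVM decision values on internal
cross-validated predictions), the standard score-to-probability mapping
for support-vector classifiers.

The trained model here is validated only on synthetic cohorts; no claim of
clinical validity transfers from them.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.compose import ColumnTransformer
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .records import Treatment

__all__ = [
    "Sex",
    "Anticoagulation",
    "Comorbidity",
    "RiskFeatures",
    "VasospasmRiskClassifier",
    "ENCODED_LENGTH",
    "features_to_frame",
    "encode_features",
    "train_risk_model",
    "predict_risk",
    "evaluate_model",
    "save_model",
    "load_model",
]


class Sex(str, Enum):
    female = "female"
    male = "male"


class Anticoagulation(str, Enum):
    none = "none"
    asa = "ASA"
    doac = "DOAC"
    antiplatelet = "antiplatelet"
    combination = "combination"


class Comorbidity(str, Enum):
    hypertension = "arterial_hypertension"
    cardiovascular = "cardiovascular_disease"
    pulmonary = "pulmonary_disease"


class RiskFeatures(BaseModel):
    """Admission-time features of the vasospasm-risk model."""

    model_config = ConfigDict(frozen=True)

    sex: Sex
    age: int = Field(ge=0, le=130)
    hh_grade: int = Field(ge=1, le=5, description="Hunt & Hess")
    fisher_grade: int = Field(ge=1, le=4)
    bni_grade: int = Field(ge=1, le=5)
    comorbidities: frozenset[Comorbidity] = frozenset()
    anticoagulation: Anticoagulation = Anticoagulation.none
    op_duration_min: float = Field(ge=0.0, le=1440.0)
    treatment: Treatment

    @field_validator("comorbidities", mode="before")
    @classmethod
    def _parse_comorbidities(cls, v):
        # Accept "none", a delimited string, or an iterable of names.
        if v is None:
            return frozenset()
        if isinstance(v, str):
            v = [s for s in v.replace(",", ";").split(";") if s.strip()]
        items = {s.strip() if isinstance(s, str) else s for s in v}
        items.discard("none")
        return frozenset(Comorbidity(i) for i in items)


# Fixed feature schema: columns of the model's input frame.
CATEGORICAL_COLUMNS = {
    "sex": [s.value for s in Sex],
    "anticoagulation": [a.value for a in Anticoagulation],
    "treatment": [t.value for t in Treatment],
}
COMORBIDITY_COLUMNS = [f"com_{c.name}" for c in Comorbidity]
ORDINAL_COLUMNS = ["hh_grade", "fisher_grade", "bni_grade"]
CONTINUOUS_COLUMNS = ["age", "op_duration_min"]
FEATURE_COLUMNS = (
    list(CATEGORICAL_COLUMNS) + COMORBIDITY_COLUMNS + ORDINAL_COLUMNS + CONTINUOUS_COLUMNS
)

#: Length of the encoded vector: one-hot levels (2 + 5 + 2), three
#: comorbidity indicators, three ordinal grades, two standardized
#: continuous features.
ENCODED_LENGTH = sum(len(v) for v in CATEGORICAL_COLUMNS.values()) + len(
    COMORBIDITY_COLUMNS
) + len(ORDINAL_COLUMNS) + len(CONTINUOUS_COLUMNS)


def features_to_frame(features: Union[RiskFeatures, Sequence[RiskFeatures]]) -> pd.DataFrame:
    """Tabulate one or more :class:`RiskFeatures` into the model's schema."""
    if isinstance(features, RiskFeatures):
        features = [features]
    rows = []
    for f in features:
        row = {
            "sex": f.sex.value,
            "anticoagulation": f.anticoagulation.value,
            "treatment": f.treatment.value,
            "hh_grade": f.hh_grade,
            "fisher_grade": f.fisher_grade,
            "bni_grade": f.bni_grade,
            "age": f.age,
            "op_duration_min": f.op_duration_min,
        }
        for c in Comorbidity:
            row[f"com_{c.name}"] = int(c in f.comorbidities)
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _validate_frame(X: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in X.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    for col, levels in CATEGORICAL_COLUMNS.items():
        bad = set(X[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown category level in {col!r}: {sorted(bad)}")
    return X[FEATURE_COLUMNS]


class VasospasmRiskClassifier(BaseEstimator, ClassifierMixin):
    """Kernel-SVM classifier of symptomatic-vasospasm risk.

    Parameters
    ----------
    kernel : str, default "rbf"
        SVC kernel.
    C : float, default 1.0
        SVC regularization strength.
    gamma : str or float, default "scale"
        RBF bandwidth; ``"scale"`` is the variance-based heuristic.
    holdout_fraction : float, default 0.25
        Fraction of the cohort reserved for the holdout evaluation.
    cv : int, default 5
        Number of stratified cross-validation folds.
    random_state : int or None
        Seed controlling the holdout split, the fold shuffling and the
        Platt-scaling internals; fixing it makes training reproducible.

    Attributes
    ----------
    pipeline_ : sklearn.pipeline.Pipeline
        Encoder + SVC fitted on the full cohort.
    classes_ : ndarray
        The two outcome labels.
    holdout_accuracy_ : float
        Accuracy of a model trained on the non-holdout rows, measured on
        the stratified holdout.
    cv_accuracies_ : ndarray of shape (cv,)
        Per-fold stratified cross-validation accuracies on the full cohort.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 1.0,
        gamma: Union[str, float] = "scale",
        holdout_fraction: float = 0.25,
        cv: int = 5,
        random_state: Optional[int] = None,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.holdout_fraction = holdout_fraction
        self.cv = cv
        self.random_state = random_state

    def _make_pipeline(self) -> Pipeline:
        encoder = ColumnTransformer(
            [
                (
                    "onehot",
                    OneHotEncoder(
                        categories=[CATEGORICAL_COLUMNS[c] for c in CATEGORICAL_COLUMNS],
                        handle_unknown="error",
                        sparse_output=False,
                    ),
                    list(CATEGORICAL_COLUMNS),
                ),
                ("indicators", "passthrough", COMORBIDITY_COLUMNS),
                ("ordinal", "passthrough", ORDINAL_COLUMNS),
                ("scale", StandardScaler(), CONTINUOUS_COLUMNS),
            ]
        )
        svc = SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            random_state=self.random_state,
        )
        # Platt scaling: sigmoid calibration of the SVM decision values,
        # fitted on internal cross-validated predictions.
        clf = CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
        return Pipeline([("encode", encoder), ("svm", clf)])

    def fit(self, X: pd.DataFrame, y) -> "VasospasmRiskClassifier":
        """Fit on a labeled cohort and record holdout + CV accuracies."""
        X = _validate_frame(X)
        y = np.asarray(y)
        if len(X) < 20:
            raise ValueError(f"cohort too small to fit and evaluate: {len(X)} rows (need >= 20)")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("cohort contains a single outcome class; cannot train")

        X_train, X_hold, y_train, y_hold = train_test_split(
            X,
            y,
            test_size=self.holdout_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        holdout_model = self._make_pipeline().fit(X_train, y_train)
        self.holdout_accuracy_ = float(holdout_model.score(X_hold, y_hold))

        folds = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        self.cv_accuracies_ = cross_val_score(
            self._make_pipeline(), X, y, cv=folds, scoring="accuracy"
        )

        self.pipeline_ = self._make_pipeline().fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(_validate_frame(X))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(_validate_frame(X))

    def predict_risk(self, features: Union[RiskFeatures, pd.DataFrame]) -> float:
        """Probability of symptomatic vasospasm for a single patient."""
        if isinstance(features, RiskFeatures):
            features = features_to_frame(features)
        proba = self.predict_proba(features)
        positive = list(self.classes_).index(self.classes_.max())
        p = float(proba[0, positive])
        assert 0.0 <= p <= 1.0
        return p

    def encode(self, features: Union[RiskFeatures, pd.DataFrame]) -> np.ndarray:
        """Encoded numeric vector(s) under the fitted schema.

        One-hot for categorical fields, 0/1 indicators for comorbidities,
        raw integers for the ordinal grades, and training-set
        standardization for the continuous fields.
        """
        check_is_fitted(self, "pipeline_")
        if isinstance(features, RiskFeatures):
            features = features_to_frame(features)
        encoded = self.pipeline_.named_steps["encode"].transform(_validate_frame(features))
        return np.asarray(encoded)

    def evaluate(self, X: pd.DataFrame, y) -> dict:
        """Accuracy and confusion counts on a held-out labeled table."""
        check_is_fitted(self, "pipeline_")
        X = _validate_frame(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("held-out table is empty")
        pred = self.pipeline_.predict(X)
        cm = confusion_matrix(y, pred, labels=self.classes_)
        accuracy = float(np.trace(cm) / cm.sum())
        return {
            "accuracy": accuracy,
            "confusion": cm,
            "n": int(len(y)),
            "labels": list(self.classes_),
        }


# -- thin functional wrappers -----------------------------------------


def encode_features(model: VasospasmRiskClassifier, features: RiskFeatures) -> np.ndarray:
    vec = model.encode(features)[0]
    assert vec.shape == (ENCODED_LENGTH,)
    return vec


def train_risk_model(
    cohort: pd.DataFrame,
    outcome_column: str = "symptomatic_vasospasm",
    seed: Optional[int] = None,
    **params,
) -> VasospasmRiskClassifier:
    """Train the risk classifier on a labeled cohort table."""
    if outcome_column not in cohort.columns:
        raise ValueError(f"cohort lacks outcome column {outcome_column!r}")
    model = VasospasmRiskClassifier(random_state=seed, **params)
    return model.fit(cohort, cohort[outcome_column].to_numpy())


def predict_risk(model: VasospasmRiskClassifier, features: RiskFeatures) -> float:
    return model.predict_risk(features)


def evaluate_model(
    model: VasospasmRiskClassifier,
    heldout: pd.DataFrame,
    outcome_column: str = "symptomatic_vasospasm",
) -> dict:
    return model.evaluate(heldout, heldout[outcome_column].to_numpy())


def save_model(model: VasospasmRiskClassifier, path: str) -> None:
    joblib.dump({"format": "costas-risk-model-v1", "model": model}, path)


def load_model(path: str) -> VasospasmRiskClassifier:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "costas-risk-model-v1":
        raise ValueError(f"{path}: not a recognised risk-model file")
    return payload["model"]
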