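"""ED triage outcome prediction: a retrainable, nonknowledge-based engine.

Predicts three (non-exclusive) binary outcomes for a patient at the triage
stage — in-hospital mortality, critical-care admission, hospitalization — from
the information available before examination: age, sex, chief complaint, time
from symptom onset, arrival mode, trauma flag, initial vital signs, and mental
status.  Each prediction is reported as a probability plus a predefined risk
band (1-5) read off band edges frozen at training time.

The engine contract is model-agnostic: logistic regression per outcome head is
the default, a shallow feed-forward network is optional.  Model artifacts are
versioned JSON documents (parameters, encoding spec, band edges) — no opaque
binaries — so a trained model is inspectable and portable.

Feature encoding is frozen (version "1"): numeric vitals are standardized with
fixed population constants (not data-dependent), missing numerics become a
zero fill plus a missingness indicator, and categorical fields are indicator
coded against frozen category lists with the first category as reference —
the design stays full-rank, so unpenalized per-head fits are identifiable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .vocabulary_preprocessing import EngineDescriptor, FeatureRecord, FeatureSpec

ENCODING_VERSION = "1"
OUTCOMES = ("mortality", "critical_care", "hospitalization")

# numeric feature -> (center, scale) frozen standardization constants
NUMERIC_FEATURES: dict[str, tuple[float, float]] = {
    "age": (50.0, 20.0),
    "onset_to_visit": (12.0, 12.0),
    "sbp": (120.0, 20.0),
    "dbp": (75.0, 15.0),
    "heart_rate": (85.0, 20.0),
    "resp_rate": (18.0, 5.0),
    "body_temperature": (37.0, 0.7),
    "spo2": (96.0, 4.0),
}

# categorical vocabularies; the first entry is the reference category and is
# not given a coordinate, keeping the design full-rank for unpenalized fits
SEX_CATEGORIES = ("female", "male")
ARRIVAL_MODES = ("walk_in", "ambulance", "transfer")
AVPU_CATEGORIES = ("A", "V", "P", "U")

# frozen 20-item chief-complaint vocabulary; unknown codes map to "other",
# which is also the reference category
CHIEF_COMPLAINTS = (
    "other",
    "fever",
    "chest_pain",
    "abdominal_pain",
    "dyspnea",
    "headache",
    "dizziness",
    "altered_mentality",
    "injury",
    "vomiting",
    "diarrhea",
    "syncope",
    "seizure",
    "back_pain",
    "urinary_symptoms",
    "weakness",
    "cough",
    "palpitations",
    "rash",
    "bleeding",
)


class DegenerateOutcomeError(ValueError):
    """An outcome column holds a single class; a classifier cannot be fit."""


class TriageFitError(RuntimeError):
    """Optimization failed to produce finite parameters."""


class EncodingVersionMismatch(ValueError):
    """Model artifact encoded with a different feature-encoding version."""


@dataclass(frozen=True)
class TriageInput:
    """One patient at the triage stage.  Vitals may be missing."""

    age: Optional[float] = None  # years
    sex: Optional[str] = None  # female | male
    chief_complaint: Optional[str] = None  # code from CHIEF_COMPLAINTS
    onset_to_visit: Optional[float] = None  # hours from symptom onset to arrival
    arrival_mode: Optional[str] = None  # ambulance | walk_in | transfer
    trauma: Optional[bool] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    body_temperature: Optional[float] = None
    spo2: Optional[float] = None
    mental_status: Optional[str] = None  # AVPU

    def __post_init__(self):
        if self.age is not None and self.age < 0:
            raise ValueError("age must be non-negative")
        if self.onset_to_visit is not None and self.onset_to_visit < 0:
            raise ValueError("onset_to_visit must be non-negative")

    @classmethod
    def from_row(cls, row) -> "TriageInput":
        kwargs = {}
        for f in fields(cls):
            v = row.get(f.name) if isinstance(row, dict) else getattr(row, f.name, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[f.name] = None
            elif f.name == "trauma":
                kwargs[f.name] = bool(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def feature_names() -> list[str]:
    """Coordinate names of the encoded vector, in order (encoding version 1)."""
    names: list[str] = []
    for n in NUMERIC_FEATURES:
        names.append(n)
        names.append(f"{n}_missing")
    names.append("trauma")
    names.extend(f"sex_{c}" for c in SEX_CATEGORIES[1:])
    names.extend(f"arrival_{c}" for c in ARRIVAL_MODES[1:])
    names.extend(f"avpu_{c}" for c in AVPU_CATEGORIES[1:])
    names.extend(f"cc_{c}" for c in CHIEF_COMPLAINTS[1:])
    return names


_FEATURE_NAMES = feature_names()
ENCODING_LENGTH = len(_FEATURE_NAMES)


def encode_triage(inp: TriageInput) -> np.ndarray:
    """Deterministic fixed-length encoding of a triage input.

    Unknown chief-complaint codes fall into the ``other`` bucket (logged via
    the returned vector only; the mapping is total, never an exception).
    """
    vec = np.zeros(ENCODING_LENGTH)
    i = 0
    for name, (center, scale) in NUMERIC_FEATURES.items():
        value = getattr(inp, name)
        if value is None:
            vec[i] = 0.0
            vec[i + 1] = 1.0
        else:
            vec[i] = (float(value) - center) / scale
            vec[i + 1] = 0.0
        i += 2
    vec[i] = 1.0 if inp.trauma else 0.0
    i += 1
    for c in SEX_CATEGORIES[1:]:
        vec[i] = 1.0 if inp.sex == c else 0.0
        i += 1
    for c in ARRIVAL_MODES[1:]:
        vec[i] = 1.0 if inp.arrival_mode == c else 0.0
        i += 1
    for c in AVPU_CATEGORIES[1:]:
        vec[i] = 1.0 if inp.mental_status == c else 0.0
        i += 1
    cc = inp.chief_complaint if inp.chief_complaint in CHIEF_COMPLAINTS else "other"
    for c in CHIEF_COMPLAINTS[1:]:
        vec[i] = 1.0 if cc == c else 0.0
        i += 1
    assert i == ENCODING_LENGTH
    return vec


def encode_frame(frame: pd.DataFrame) -> np.ndarray:
    """Encode a dataset (one row per visit) into the design matrix."""
    return np.vstack([encode_triage(TriageInput.from_row(row)) for row in frame.to_dict("records")])


# ---------------------------------------------------------------------------
# model


@dataclass
class OutcomeHead:
    coef: list[float]
    intercept: float
    band_edges: list[float]
    train_auroc: Optional[float] = None
    test_auroc: Optional[float] = None
    # shallow-network weights (input->hidden, hidden->output), empty for logistic
    hidden_coef: list[list[float]] = field(default_factory=list)
    hidden_intercept: list[float] = field(default_factory=list)


@dataclass
class TriageModel:
    model_kind: str  # logistic | shallow_network
    encoding_version: str
    feature_names: list[str]
    heads: dict[str, OutcomeHead]
    n_train: int
    n_test: int
    seed: int
    test_fraction: float
    version: str = "1"

    def to_json(self, indent: int = 2) -> str:
        doc = {
            "artifact": "cane-triage-model",
            "version": self.version,
            "model_kind": self.model_kind,
            "encoding_version": self.encoding_version,
            "feature_names": self.feature_names,
            "training": {
                "n_train": self.n_train,
                "n_test": self.n_test,
                "seed": self.seed,
                "test_fraction": self.test_fraction,
            },
            "heads": {
                name: {
                    "coef": head.coef,
                    "intercept": head.intercept,
                    "band_edges": head.band_edges,
                    "train_auroc": head.train_auroc,
                    "test_auroc": head.test_auroc,
                    "hidden_coef": head.hidden_coef,
                    "hidden_intercept": head.hidden_intercept,
                }
                for name, head in self.heads.items()
            },
        }
        return json.dumps(doc, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "TriageModel":
        doc = json.loads(text)
        heads = {
            name: OutcomeHead(
                coef=h["coef"],
                intercept=h["intercept"],
                band_edges=h["band_edges"],
                train_auroc=h.get("train_auroc"),
                test_auroc=h.get("test_auroc"),
                hidden_coef=h.get("hidden_coef", []),
                hidden_intercept=h.get("hidden_intercept", []),
            )
            for name, h in doc["heads"].items()
        }
        return cls(
            model_kind=doc["model_kind"],
            encoding_version=doc["encoding_version"],
            feature_names=doc["feature_names"],
            heads=heads,
            n_train=doc["training"]["n_train"],
            n_test=doc["training"]["n_test"],
            seed=doc["training"]["seed"],
            test_fraction=doc["training"]["test_fraction"],
            version=doc.get("version", "1"),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TriageModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class TriagePrediction:
    probabilities: dict[str, float]
    risk_band: int  # 1-5; the worst per-outcome band
    outcome_bands: dict[str, int]
    model_version: str


@dataclass(frozen=True)
class TriageTrainingConfig:
    seed: int = 0
    test_fraction: float = 0.25
    model_kind: str = "logistic"  # logistic | shallow_network
    hidden_units: int = 8


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _head_probability(head: OutcomeHead, x: np.ndarray) -> float:
    if head.hidden_coef:
        w1 = np.asarray(head.hidden_coef)
        b1 = np.asarray(head.hidden_intercept)
        h = np.maximum(x @ w1 + b1, 0.0)  # relu
        z = h @ np.asarray(head.coef) + head.intercept
    else:
        z = float(np.dot(head.coef, x)) + head.intercept
    return float(_sigmoid(np.asarray(z)))


def assign_risk_band(probability: float, band_edges: list[float]) -> int:
    """Risk band = 1 + number of edges strictly below the probability.

    With four edges (training-set quintiles) this yields bands 1-5.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability {probability} outside [0, 1]")
    edges = list(band_edges)
    if edges != sorted(edges):
        raise ValueError("band_edges must be non-decreasing")
    return 1 + sum(1 for e in edges if e < probability)


def fit_triage_model(dataset: pd.DataFrame, config: TriageTrainingConfig) -> TriageModel:
    """Train one head per outcome on a tidy visit-level table.

    The table carries one column per :class:`TriageInput` field plus the three
    0/1 outcome columns.  Rows are split train/test by a seeded permutation;
    heads are unpenalized logistic fits (or a small ReLU network); per-head
    AUROC on both splits and quintile band edges of the training predictions
    are frozen into the artifact.  Deterministic given the config seed.
    """
    for outcome in OUTCOMES:
        if outcome not in dataset.columns:
            raise ValueError(f"dataset lacks outcome column {outcome!r}")
        if dataset[outcome].nunique() < 2:
            raise DegenerateOutcomeError(f"outcome {outcome!r} has a single class in the dataset")

    x = encode_frame(dataset)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_test = int(round(len(dataset) * config.test_fraction))
    test_idx, train_idx = order[:n_test], order[n_test:]
    if len(train_idx) == 0:
        raise ValueError("empty training split")

    heads: dict[str, OutcomeHead] = {}
    for outcome in OUTCOMES:
        y = dataset[outcome].to_numpy().astype(int)
        if y[train_idx].min() == y[train_idx].max():
            raise DegenerateOutcomeError(f"outcome {outcome!r} has a single class in the training split")
        if config.model_kind == "logistic":
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-8)
            clf.fit(x[train_idx], y[train_idx])
            coef = clf.coef_[0]
            if not np.all(np.isfinite(coef)) or not np.isfinite(clf.intercept_[0]):
                raise TriageFitError(f"non-finite parameters for outcome {outcome!r}")
            head = OutcomeHead(coef=coef.tolist(), intercept=float(clf.intercept_[0]), band_edges=[])
            p_train = clf.predict_proba(x[train_idx])[:, 1]
            p_test = clf.predict_proba(x[test_idx])[:, 1] if len(test_idx) else np.array([])
        elif config.model_kind == "shallow_network":
            clf = MLPClassifier(
                hidden_layer_sizes=(config.hidden_units,),
                activation="relu",
                solver="lbfgs",
                max_iter=2000,
                random_state=config.seed,
            )
            clf.fit(x[train_idx], y[train_idx])
            if not all(np.all(np.isfinite(c)) for c in clf.coefs_):
                raise TriageFitError(f"non-finite parameters for outcome {outcome!r}")
            head = OutcomeHead(
                coef=clf.coefs_[1][:, 0].tolist(),
                intercept=float(clf.intercepts_[1][0]),
                band_edges=[],
                hidden_coef=clf.coefs_[0].tolist(),
                hidden_intercept=clf.intercepts_[0].tolist(),
            )
            p_train = clf.predict_proba(x[train_idx])[:, 1]
            p_test = clf.predict_proba(x[test_idx])[:, 1] if len(test_idx) else np.array([])
        else:
            raise ValueError(f"unknown model_kind {config.model_kind!r}")

        head.band_edges = [float(q) for q in np.quantile(p_train, [0.2, 0.4, 0.6, 0.8])]
        head.train_auroc = float(roc_auc_score(y[train_idx], p_train))
        if len(test_idx) and y[test_idx].min() != y[test_idx].max():
            head.test_auroc = float(roc_auc_score(y[test_idx], p_test))
        heads[outcome] = head

    return TriageModel(
        model_kind=config.model_kind,
        encoding_version=ENCODING_VERSION,
        feature_names=_FEATURE_NAMES,
        heads=heads,
        n_train=int(len(train_idx)),
        n_test=int(len(test_idx)),
        seed=config.seed,
        test_fraction=config.test_fraction,
    )


def predict_triage(model: TriageModel, inp: TriageInput) -> TriagePrediction:
    """Probabilities for the three outcomes plus the predefined risk band.

    The headline band is the worst (maximum) per-outcome band, so a patient
    extreme on any single outcome surfaces as high risk.
    """
    if model.encoding_version != ENCODING_VERSION:
        raise EncodingVersionMismatch(
            f"model encoded with version {model.encoding_version!r}, encoder is {ENCODING_VERSION!r}"
        )
    x = encode_triage(inp)
    probabilities = {}
    bands = {}
    for outcome, head in model.heads.items():
        p = _head_probability(head, x)
        probabilities[outcome] = p
        bands[outcome] = assign_risk_band(p, head.band_edges)
    return TriagePrediction(
        probabilities=probabilities,
        risk_band=max(bands.values()),
        outcome_bands=bands,
        model_version=model.version,
    )


# ---------------------------------------------------------------------------
# plugin surface

TRIAGE_DESCRIPTOR = EngineDescriptor(
    engine_name="triage",
    version="1",
    kind="nonknowledge_based",
    required_features=(
        FeatureSpec("age", "a", kind="demographic"),
        FeatureSpec("sex", kind="demographic"),
        FeatureSpec("arrival_mode", kind="demographic", required=False),
        FeatureSpec("chief_complaint", "{coded}", required=False),
        FeatureSpec("onset_to_visit", "h", required=False),
        FeatureSpec("trauma", "{coded}", required=False),
        FeatureSpec("sbp", "mm[Hg]", required=False),
        FeatureSpec("dbp", "mm[Hg]", required=False),
        FeatureSpec("heart_rate", "/min", required=False),
        FeatureSpec("resp_rate", "/min", required=False),
        FeatureSpec("body_temperature", "Cel", required=False),
        FeatureSpec("spo2", "%", required=False),
        FeatureSpec("mental_status_avpu", "{coded}", required=False),
    ),
    lookback_hours=24.0,
)


def input_from_feature_record(record: FeatureRecord) -> TriageInput:
    trauma = record.value("trauma")
    return TriageInput(
        age=record.value("age"),
        sex=record.value("sex"),
        chief_complaint=record.value("chief_complaint"),
        onset_to_visit=record.value("onset_to_visit"),
        arrival_mode=record.value("arrival_mode"),
        trauma=None if trauma is None else trauma in (True, "Y", "true"),
        sbp=record.value("sbp"),
        dbp=record.value("dbp"),
        heart_rate=record.value("heart_rate"),
        resp_rate=record.value("resp_rate"),
        body_temperature=record.value("body_temperature"),
        spo2=record.value("spo2"),
        mental_status=record.value("mental_status_avpu"),
    )


def build_engine(model: TriageModel):
    """Plugin entry point factory: bind a trained model, get FeatureRecord -> TriagePrediction."""

    def run(record: FeatureRecord) -> TriagePrediction:
        return predict_triage(model, input_from_feature_record(record))

    return run
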