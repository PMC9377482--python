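"""Synthetic ED/inpatient encounters with known ground truth.

Every other module is testable offline against cohorts produced here: FHIR
bundles carrying the full 14-item sepsis input schema, triage training tables
sampled from a known logistic outcome model, and OMOP-like relational stores
consistent with the generated cohort.

Two properties make the fixtures usable as oracles rather than mere noise:

* **Independent scoring oracle.**  Expected screening flags, qSOFA and SOFA
  totals are computed at generation time by straight-line ``if/elif`` code in
  this module — deliberately a second implementation, sharing nothing with the
  table-driven rule engine it is later compared against.
* **Seed determinism.**  Every sample is drawn from
  ``numpy.random.default_rng([seed, index])``; identical (profile, index)
  always yields identical bundles.

Vitals and labs are drawn from truncated normal distributions with separate
"normal" and "deranged" parameter sets per septic status; the ranges are
textbook-plausible, which is all the acceptance properties require (they are
oracle-relative, not epidemiologic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Optional

import numpy as np
import pandas as pd

from .federated_summary import LocalStore
from .fhir_io import (
    CodedValue,
    EncounterResource,
    FhirBundle,
    MedicationRequestResource,
    ObservationResource,
    PatientResource,
    Quantity,
    ServiceRequestResource,
)
from .triage_engine import (
    ARRIVAL_MODES,
    AVPU_CATEGORIES,
    CHIEF_COMPLAINTS,
    SEX_CATEGORIES,
    TriageInput,
    encode_triage,
    feature_names,
)

LOINC = "http://loinc.org"
SNOMED = "http://snomed.info/sct"
ATC = "http://www.whocc.no/atc"

# all generated events sit in a 6 h window ending at this reference instant
REFERENCE_TIME = datetime(2024, 3, 1, 12, 0, tzinfo=timezone.utc)

_LOINC_BY_FEATURE = {
    "gcs": ("9269-2", "{score}"),
    "sbp": ("8480-6", "mm[Hg]"),
    "dbp": ("8462-4", "mm[Hg]"),
    "resp_rate": ("9279-1", "/min"),
    "heart_rate": ("8867-4", "/min"),
    "body_temperature": ("8310-5", "Cel"),
    "pao2": ("2703-1", "mm[Hg]"),
    "fio2": ("19994-3", "1"),
    "platelets": ("777-3", "10*3/uL"),
    "creatinine": ("2160-0", "mg/dL"),
    "total_bilirubin": ("1975-2", "mg/dL"),
    "lactate": ("2524-7", "mmol/L"),
    "spo2": ("2708-6", "%"),
}

LABS = ("pao2", "fio2", "platelets", "creatinine", "total_bilirubin", "lactate")

# antibiotic agents: ATC code, OMOP-like drug concept id
ANTIBIOTIC_DRUGS = (
    ("J01CR05", 1746114),  # piperacillin/tazobactam
    ("J01DD04", 1777806),  # ceftriaxone
    ("J01DH02", 1775741),  # meropenem
    ("J01MA02", 1797513),  # ciprofloxacin
)
VASOPRESSOR_ATC = "C01CA03"  # norepinephrine
BLOOD_CULTURE_SNOMED = "30088009"
SEPSIS_CONDITION_CONCEPT = 132797

# (mean, sd, low, high) truncation bounds chosen inside the engine's
# plausibility ranges
_VITAL_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "body_temperature": {"normal": (36.9, 0.4, 35.0, 41.0), "deranged": (38.7, 0.7, 35.5, 41.5)},
    "sbp": {"normal": (125, 15, 80, 200), "deranged": (92, 16, 50, 160)},
    "dbp": {"normal": (75, 10, 45, 120), "deranged": (55, 10, 25, 100)},
    "resp_rate": {"normal": (16, 3, 8, 30), "deranged": (26, 5, 10, 50)},
    "heart_rate": {"normal": (80, 12, 45, 130), "deranged": (115, 15, 60, 180)},
    "spo2": {"normal": (97, 1.5, 90, 100), "deranged": (91, 3, 70, 100)},
    "pao2": {"normal": (95, 10, 60, 140), "deranged": (72, 15, 40, 120)},
    "platelets": {"normal": (250, 60, 80, 600), "deranged": (105, 60, 5, 400)},
    "creatinine": {"normal": (0.9, 0.2, 0.3, 2.0), "deranged": (2.3, 1.3, 0.4, 9.0)},
    "total_bilirubin": {"normal": (0.7, 0.3, 0.1, 2.0), "deranged": (2.6, 2.2, 0.2, 14.0)},
    "lactate": {"normal": (1.2, 0.4, 0.3, 3.0), "deranged": (3.6, 1.6, 0.5, 12.0)},
}


@dataclass(frozen=True)
class CohortProfile:
    """The study conditions a generated cohort emulates."""

    n: int = 200
    sepsis_prevalence: float = 0.3
    seed: int = 0
    # order probabilities per order type, (P | septic, P | non-septic)
    p_blood_culture: tuple[float, float] = (0.9, 0.08)
    p_antibiotics: tuple[float, float] = (0.85, 0.1)
    p_vasopressor: tuple[float, float] = (0.35, 0.01)
    lab_missingness: float = 0.1  # per-lab probability of absence
    antibiotic_mixture: tuple[tuple[str, float], ...] = (
        ("J01CR05", 0.4),
        ("J01DD04", 0.3),
        ("J01DH02", 0.2),
        ("J01MA02", 0.1),
    )
    p_death: tuple[float, float] = (0.25, 0.02)
    p_admission: tuple[float, float] = (0.75, 0.2)
    # triage outcome model: per-outcome intercept + sparse coefficients over
    # the frozen encoding's coordinate names
    triage_intercepts: tuple[tuple[str, float], ...] = (
        ("mortality", -2.0),
        ("critical_care", -1.8),
        ("hospitalization", -0.8),
    )
    # effects live on the standardized vital/demographic coordinates, where a
    # cohort of thousands pins them down tightly; category effects are left
    # null in the generating model
    triage_coefficients: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        (
            "mortality",
            (("age", 0.9), ("sbp", -0.7), ("spo2", -0.8), ("resp_rate", 0.5), ("heart_rate", 0.4)),
        ),
        (
            "critical_care",
            (
                ("age", 0.5),
                ("sbp", -0.6),
                ("spo2", -0.6),
                ("resp_rate", 0.6),
                ("heart_rate", 0.4),
                ("body_temperature", 0.3),
            ),
        ),
        (
            "hospitalization",
            (("age", 0.8), ("sbp", -0.3), ("body_temperature", 0.4), ("dbp", -0.2), ("onset_to_visit", 0.2)),
        ),
    )

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.sepsis_prevalence <= 1.0:
            raise ValueError("sepsis_prevalence must lie in [0, 1]")
        for pair in (self.p_blood_culture, self.p_antibiotics, self.p_vasopressor, self.p_death, self.p_admission):
            if not all(0.0 <= p <= 1.0 for p in pair):
                raise ValueError("order/outcome probabilities must lie in [0, 1]")
        if abs(sum(w for _, w in self.antibiotic_mixture) - 1.0) > 1e-9:
            raise ValueError("antibiotic mixture weights must sum to 1")

    def coefficient_vector(self, outcome: str) -> tuple[float, np.ndarray]:
        """(intercept, dense coefficient vector) of the generating model."""
        names = feature_names()
        vec = np.zeros(len(names))
        coeffs = dict(self.triage_coefficients)[outcome]
        for name, value in coeffs:
            vec[names.index(name)] = value
        return dict(self.triage_intercepts)[outcome], vec


@dataclass
class GroundTruth:
    """Generation-time truth for one patient, from the independent oracle."""

    patient_id: str
    septic: bool
    expected_screen_flag: bool
    expected_qsofa: int
    expected_sofa: int
    blood_culture_ordered: bool
    antibiotics_ordered: bool
    vasopressor_ordered: bool
    antibiotic_atc: Optional[str]
    died: bool
    admitted: bool


@dataclass
class PatientSample:
    """Raw sampled values before FHIR packaging."""

    patient_id: str
    values: dict[str, Optional[float]]  # 11 measured inputs, None when missing
    blood_culture_ordered: bool
    antibiotics_ordered: bool
    vasopressor_ordered: bool
    antibiotic_atc: Optional[str]
    septic: bool
    died: bool
    admitted: bool
    age: int
    sex: str
    truth: GroundTruth = field(init=False)

    def __post_init__(self):
        self.truth = GroundTruth(
            patient_id=self.patient_id,
            septic=self.septic,
            expected_screen_flag=oracle_screen(
                self.values.get("body_temperature"), self.blood_culture_ordered, self.antibiotics_ordered
            ),
            expected_qsofa=oracle_qsofa(
                self.values.get("sbp"), self.values.get("resp_rate"), self.values.get("gcs")
            ),
            expected_sofa=oracle_sofa(self.values, self.vasopressor_ordered),
            blood_culture_ordered=self.blood_culture_ordered,
            antibiotics_ordered=self.antibiotics_ordered,
            vasopressor_ordered=self.vasopressor_ordered,
            antibiotic_atc=self.antibiotic_atc,
            died=self.died,
            admitted=self.admitted,
        )


# ---------------------------------------------------------------------------
# the independent straight-line oracle (no tables, no engine imports)


def oracle_screen(temperature: Optional[float], culture: bool, antibiotics: bool) -> bool:
    if temperature is None:
        return False
    return temperature > 37.5 and (culture or antibiotics)


def oracle_qsofa(sbp: Optional[float], resp_rate: Optional[float], gcs: Optional[float]) -> int:
    score = 0
    if sbp is not None and sbp <= 100:
        score += 1
    if resp_rate is not None and resp_rate >= 22:
        score += 1
    if gcs is not None and gcs < 15:
        score += 1
    return score


def oracle_sofa(values: dict[str, Optional[float]], vasopressor_ordered: bool) -> int:
    total = 0

    pao2, fio2 = values.get("pao2"), values.get("fio2")
    if pao2 is not None and fio2 is not None and fio2 > 0:
        ratio = pao2 / fio2
        if ratio < 100:
            total += 4
        elif ratio < 200:
            total += 3
        elif ratio < 300:
            total += 2
        elif ratio < 400:
            total += 1

    plt = values.get("platelets")
    if plt is not None:
        if plt < 20:
            total += 4
        elif plt < 50:
            total += 3
        elif plt < 100:
            total += 2
        elif plt < 150:
            total += 1

    bili = values.get("total_bilirubin")
    if bili is not None:
        if bili >= 12.0:
            total += 4
        elif bili >= 6.0:
            total += 3
        elif bili >= 2.0:
            total += 2
        elif bili >= 1.2:
            total += 1

    if vasopressor_ordered:
        total += 3
    else:
        sbp, dbp = values.get("sbp"), values.get("dbp")
        if sbp is not None and dbp is not None and (sbp + 2 * dbp) / 3 < 70:
            total += 1

    gcs = values.get("gcs")
    if gcs is not None:
        if gcs < 6:
            total += 4
        elif gcs < 10:
            total += 3
        elif gcs < 13:
            total += 2
        elif gcs < 15:
            total += 1

    cr = values.get("creatinine")
    if cr is not None:
        if cr >= 5.0:
            total += 4
        elif cr >= 3.5:
            total += 3
        elif cr >= 2.0:
            total += 2
        elif cr >= 1.2:
            total += 1

    return total


# ---------------------------------------------------------------------------
# sampling


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))  # pragma: no cover - pathological parameters


def _patient_rng(profile: CohortProfile, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([profile.seed, stream, index])


def sample_patient(profile: CohortProfile, index: int) -> PatientSample:
    """Draw one patient's raw values, orders, and outcomes; truth included."""
    rng = _patient_rng(profile, index)
    septic = bool(rng.random() < profile.sepsis_prevalence)
    group = "deranged" if septic else "normal"

    values: dict[str, Optional[float]] = {}
    for name, dists in _VITAL_DISTRIBUTIONS.items():
        mean, sd, lo, hi = dists[group]
        v = _truncated_normal(rng, mean, sd, lo, hi)
        if name in ("sbp", "dbp", "resp_rate", "heart_rate", "platelets", "pao2", "spo2"):
            v = float(round(v))
        else:
            v = round(v, 1)
        values[name] = v

    # GCS: discrete; septic patients are sometimes obtunded
    if septic:
        values["gcs"] = float(rng.choice([15, 14, 12, 8, 5], p=[0.35, 0.25, 0.2, 0.15, 0.05]))
    else:
        values["gcs"] = float(rng.choice([15, 14], p=[0.95, 0.05]))

    # FiO2: room air unless respiratory support
    if septic:
        values["fio2"] = float(rng.choice([0.21, 0.4, 0.6], p=[0.5, 0.3, 0.2]))
    else:
        values["fio2"] = 0.21

    for lab in LABS:
        if rng.random() < profile.lab_missingness:
            values[lab] = None

    j = 0 if septic else 1
    culture = bool(rng.random() < profile.p_blood_culture[j])
    antibiotics = bool(rng.random() < profile.p_antibiotics[j])
    vasopressor = bool(rng.random() < profile.p_vasopressor[j])
    antibiotic_atc = None
    if antibiotics:
        codes = [c for c, _ in profile.antibiotic_mixture]
        weights = [w for _, w in profile.antibiotic_mixture]
        antibiotic_atc = str(rng.choice(codes, p=weights))

    died = bool(rng.random() < profile.p_death[j])
    admitted = bool(died or rng.random() < profile.p_admission[j])

    return PatientSample(
        patient_id=f"p{index:05d}",
        values=values,
        blood_culture_ordered=culture,
        antibiotics_ordered=antibiotics,
        vasopressor_ordered=vasopressor,
        antibiotic_atc=antibiotic_atc,
        septic=septic,
        died=died,
        admitted=admitted,
        age=int(_truncated_normal(rng, 62, 16, 18, 95)),
        sex=str(rng.choice(["female", "male"])),
    )


def generate_patient_bundle(profile: CohortProfile, index: int) -> tuple[FhirBundle, GroundTruth]:
    """Package one sampled patient as a FHIR collection bundle.

    The bundle holds a Patient, an emergency Encounter, one final Observation
    per present measured input (timestamped inside the 6 h window before
    :data:`REFERENCE_TIME`), and order resources for sampled flags.
    """
    sample = sample_patient(profile, index)
    rng = _patient_rng(profile, index, stream=1)
    pid = sample.patient_id
    birth_year = REFERENCE_TIME.year - sample.age

    entries: list = [
        PatientResource(
            resource_id=pid,
            birth_date=date(birth_year, 1, 1),
            administrative_sex=sample.sex,
        ),
        EncounterResource(
            resource_id=f"{pid}-enc",
            subject_ref=pid,
            class_code="emergency",
            start_time=REFERENCE_TIME - timedelta(hours=6),
            arrival_mode="amb" if sample.vasopressor_ordered or rng.random() < 0.3 else "walk",
        ),
    ]

    for name, value in sample.values.items():
        if value is None:
            continue
        code, unit = _LOINC_BY_FEATURE[name]
        entries.append(
            ObservationResource(
                resource_id=f"{pid}-{name}",
                subject_ref=pid,
                code=CodedValue(system=LOINC, code=code),
                value_quantity=Quantity(value=value, unit=unit),
                effective_time=REFERENCE_TIME - timedelta(minutes=float(rng.uniform(5, 355))),
                status="final",
            )
        )

    order_time = REFERENCE_TIME - timedelta(minutes=float(rng.uniform(5, 355)))
    if sample.blood_culture_ordered:
        entries.append(
            ServiceRequestResource(
                resource_id=f"{pid}-bcx",
                subject_ref=pid,
                procedure_code=CodedValue(system=SNOMED, code=BLOOD_CULTURE_SNOMED),
                authored_time=order_time,
                status="active",
            )
        )
    if sample.antibiotics_ordered:
        entries.append(
            MedicationRequestResource(
                resource_id=f"{pid}-abx",
                subject_ref=pid,
                medication_code=CodedValue(system=ATC, code=sample.antibiotic_atc),
                authored_time=order_time,
                status="active",
            )
        )
    if sample.vasopressor_ordered:
        entries.append(
            MedicationRequestResource(
                resource_id=f"{pid}-vaso",
                subject_ref=pid,
                medication_code=CodedValue(system=ATC, code=VASOPRESSOR_ATC),
                authored_time=order_time,
                status="active",
            )
        )

    bundle = FhirBundle(bundle_id=f"bundle-{pid}", bundle_type="collection", entries=entries)
    return bundle, sample.truth


def generate_cohort(profile: CohortProfile) -> tuple[list[FhirBundle], pd.DataFrame]:
    """n patient bundles plus the ground-truth table (one row per patient)."""
    bundles = []
    rows = []
    for i in range(profile.n):
        bundle, truth = generate_patient_bundle(profile, i)
        bundles.append(bundle)
        rows.append(vars(truth))
    return bundles, pd.DataFrame(rows)


def generate_local_store(profile: CohortProfile, institution_offset: int = 0) -> LocalStore:
    """An OMOP-like store consistent with the sampled cohort.

    Septic patients get a sepsis condition row; ordered antibiotics become
    drug exposures with the profile's per-drug mixture; deaths and inpatient
    visits follow the sampled outcomes.  ``institution_offset`` shifts patient
    indices so distinct institutions hold disjoint pseudo-populations.
    """
    concept_by_atc = dict(ANTIBIOTIC_DRUGS)
    persons, visits, measurements, drugs, conditions, deaths = [], [], [], [], [], []
    t0 = REFERENCE_TIME - timedelta(hours=6)

    for i in range(profile.n):
        sample = sample_patient(profile, institution_offset + i)
        pid = sample.patient_id
        persons.append(
            {
                "person_id": pid,
                "birth_date": f"{REFERENCE_TIME.year - sample.age}-01-01",
                "sex_concept": 8532 if sample.sex == "female" else 8507,
            }
        )
        visits.append(
            {
                "visit_id": f"{pid}-v1",
                "person_id": pid,
                "visit_class": "emergency",
                "start": t0.isoformat(),
                "end": REFERENCE_TIME.isoformat(),
            }
        )
        if sample.admitted:
            visits.append(
                {
                    "visit_id": f"{pid}-v2",
                    "person_id": pid,
                    "visit_class": "inpatient",
                    "start": REFERENCE_TIME.isoformat(),
                    "end": (REFERENCE_TIME + timedelta(days=5)).isoformat(),
                }
            )
        if sample.septic:
            conditions.append(
                {
                    "person_id": pid,
                    "condition_concept_id": SEPSIS_CONDITION_CONCEPT,
                    "time": REFERENCE_TIME.isoformat(),
                }
            )
        lactate = sample.values.get("lactate")
        if lactate is not None:
            measurements.append(
                {
                    "person_id": pid,
                    "concept_id": 3047181,
                    "value": lactate,
                    "unit": "mmol/L",
                    "time": REFERENCE_TIME.isoformat(),
                }
            )
        if sample.antibiotics_ordered and sample.antibiotic_atc in concept_by_atc:
            drugs.append(
                {
                    "person_id": pid,
                    "drug_concept_id": concept_by_atc[sample.antibiotic_atc],
                    "time": REFERENCE_TIME.isoformat(),
                }
            )
        if sample.died:
            deaths.append({"person_id": pid, "time": (REFERENCE_TIME + timedelta(days=3)).isoformat()})

    def frame(rows, table):
        from .federated_summary import TABLE_COLUMNS

        return pd.DataFrame(rows, columns=TABLE_COLUMNS[table]) if rows else pd.DataFrame(columns=TABLE_COLUMNS[table])

    store = LocalStore(
        person=frame(persons, "person"),
        visit=frame(visits, "visit"),
        measurement=frame(measurements, "measurement"),
        drug_exposure=frame(drugs, "drug_exposure"),
        condition=frame(conditions, "condition"),
        death=frame(deaths, "death"),
    )
    store.validate()
    return store


def sepsis_cohort_spec():
    """The fixture cohort: everyone carrying the sepsis condition concept."""
    from .federated_summary import CohortSpec

    return CohortSpec(name="sepsis", condition_concepts=(SEPSIS_CONDITION_CONCEPT,))


# ---------------------------------------------------------------------------
# triage training data


def generate_triage_dataset(profile: CohortProfile) -> pd.DataFrame:
    """A tidy visit-level table with outcomes drawn from the known logistic model.

    One row per visit: the :class:`~cane.triage_engine.TriageInput` columns
    plus the three 0/1 outcome columns.  Outcome probabilities come from the
    profile's intercepts/coefficients applied to the frozen encoding, so the
    generating parameters are recoverable by the fitting code.
    """
    rng = np.random.default_rng([profile.seed, 2])
    rows = []
    for _ in range(profile.n):
        inp = TriageInput(
            age=float(int(_truncated_normal(rng, 55, 21, 18, 95))),
            sex=str(rng.choice(SEX_CATEGORIES)),
            chief_complaint=str(rng.choice(CHIEF_COMPLAINTS)),
            onset_to_visit=round(float(rng.exponential(12.0)), 1),
            arrival_mode=str(rng.choice(ARRIVAL_MODES, p=[0.55, 0.35, 0.10])),
            trauma=bool(rng.random() < 0.15),
            sbp=float(round(_truncated_normal(rng, 125, 22, 60, 220))),
            dbp=float(round(_truncated_normal(rng, 76, 14, 35, 130))),
            heart_rate=float(round(_truncated_normal(rng, 88, 18, 40, 180))),
            resp_rate=float(round(_truncated_normal(rng, 18, 4, 8, 45))),
            body_temperature=round(_truncated_normal(rng, 37.1, 0.7, 35.0, 41.0), 1),
            spo2=float(round(_truncated_normal(rng, 96, 3, 75, 100))),
            mental_status=str(rng.choice(AVPU_CATEGORIES, p=[0.86, 0.08, 0.04, 0.02])),
        )
        x = encode_triage(inp)
        row = {f: getattr(inp, f) for f in (
            "age", "sex", "chief_complaint", "onset_to_visit", "arrival_mode", "trauma",
            "sbp", "dbp", "heart_rate", "resp_rate", "body_temperature", "spo2", "mental_status",
        )}
        for outcome, _ in profile.triage_intercepts:
            intercept, coef = profile.coefficient_vector(outcome)
            p = 1.0 / (1.0 + math.exp(-(intercept + float(coef @ x))))
            row[outcome] = int(rng.random() < p)
            row[f"p_{outcome}"] = p  # generative truth, dropped before fitting
        rows.append(row)
    return pd.DataFrame(rows)
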