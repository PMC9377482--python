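"""Convert a FHIR bundle into the canonical feature record an engine declares.

This is the preprocessing stage of the platform: code mapping against a bundled
mini-vocabulary (LOINC/SNOMED → canonical feature names with OMOP concept ids),
unit normalization into each feature's canonical unit, and latest-value
selection inside the engine's lookback window.  Order-type features (blood
culture, antibiotics, vasopressors) are resolved by code-class membership
(ATC prefixes) rather than point lookups.

Missingness is data, never an exception: required features absent from the
bundle land in ``FeatureRecord.missing`` and the preprocessing log.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources as importlib_resources
from typing import Optional, Union

from .fhir_io import (
    CodedValue,
    EncounterResource,
    FhirBundle,
    MedicationRequestResource,
    ObservationResource,
    PatientResource,
    ServiceRequestResource,
)

# Coarse responsiveness scale mapped onto Glasgow Coma Scale totals.
# A=alert, V=responds to voice, P=responds to pain, U=unresponsive.
AVPU_TO_GCS = {"A": 15, "V": 12, "P": 8, "U": 3}

# ATC prefix classes: systemic antibacterials, and adrenergic/cardiac stimulant
# vasopressors-inotropes.  The platform treats class membership, not single codes.
ANTIBIOTIC_ATC_PREFIXES = ("J01",)
VASOPRESSOR_ATC_PREFIXES = ("C01CA",)
BLOOD_CULTURE_CODES = frozenset({"30088009"})  # SNOMED: blood culture

ATC_SYSTEM = "http://www.whocc.no/atc"


class UnitConversionError(ValueError):
    """No registered conversion between the two named units."""

    def __init__(self, from_unit: str, to_unit: str):
        super().__init__(f"no unit conversion registered from {from_unit!r} to {to_unit!r}")
        self.from_unit = from_unit
        self.to_unit = to_unit


_FORMULAS = {
    "identity": lambda v: v,
    "fahrenheit_to_celsius": lambda v: (v - 32.0) * 5.0 / 9.0,
    "celsius_to_fahrenheit": lambda v: v * 9.0 / 5.0 + 32.0,
    "percent_to_fraction": lambda v: v / 100.0,
    "fraction_to_percent": lambda v: v * 100.0,
    "kilopascal_to_mmhg": lambda v: v * 7.50062,
    "mmhg_to_kilopascal": lambda v: v / 7.50062,
}


@dataclass(frozen=True)
class ConceptMapping:
    """One row of the bundled vocabulary: a source code and its canonical identity."""

    source_system: str
    source_code: str
    feature_name: str
    omop_concept_id: int
    canonical_unit: str


@dataclass(frozen=True)
class FeatureSpec:
    """One feature an engine declares: canonical name, unit, and whether required."""

    name: str
    unit: str = ""
    required: bool = True
    kind: str = "observation"  # observation | coded | order | demographic


@dataclass(frozen=True)
class EngineDescriptor:
    """What an engine needs from preprocessing: its feature schema and lookback."""

    engine_name: str
    version: str
    kind: str  # knowledge_based | nonknowledge_based
    required_features: tuple[FeatureSpec, ...]
    lookback_hours: float = 24.0

    def __post_init__(self):
        names = [f.name for f in self.required_features]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate feature names in descriptor {self.engine_name!r}")
        if self.lookback_hours <= 0:
            raise ValueError("lookback_hours must be positive")
        if self.kind not in ("knowledge_based", "nonknowledge_based"):
            raise ValueError(f"unknown engine kind {self.kind!r}")

    def feature_names(self) -> list[str]:
        return [f.name for f in self.required_features]


@dataclass
class FeatureValue:
    value: Union[float, str, bool]
    unit: str
    observed_time: Optional[datetime] = None
    provenance: str = ""  # resource id the value came from


@dataclass
class FeatureRecord:
    """Canonical, unit-normalized per-patient feature set for one engine."""

    patient_id: str
    reference_time: datetime
    features: dict[str, FeatureValue] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)
    log: list[str] = field(default_factory=list)

    def value(self, name: str, default=None):
        fv = self.features.get(name)
        return fv.value if fv is not None else default


class Vocabulary:
    """The bundled concept vocabulary plus the unit-conversion registry."""

    def __init__(self, mappings: list[ConceptMapping], conversions: dict[tuple[str, str], str]):
        self._by_code: dict[tuple[str, str], ConceptMapping] = {}
        for m in mappings:
            key = (m.source_system, m.source_code)
            if key in self._by_code:
                raise ValueError(f"duplicate vocabulary entry for {key}")
            if m.omop_concept_id <= 0:
                raise ValueError(f"non-positive OMOP concept id for {key}")
            self._by_code[key] = m
        self._by_feature = {m.feature_name: m for m in mappings}
        self._conversions = conversions

    @classmethod
    def bundled(cls) -> "Vocabulary":
        pkg = importlib_resources.files("cane.data")
        mappings = []
        with (pkg / "vocabulary.csv").open() as fh:
            for row in csv.DictReader(fh):
                mappings.append(
                    ConceptMapping(
                        source_system=row["source_system"],
                        source_code=row["source_code"],
                        feature_name=row["feature_name"],
                        omop_concept_id=int(row["omop_concept_id"]),
                        canonical_unit=row["canonical_unit"],
                    )
                )
        conversions = {}
        with (pkg / "unit_conversions.csv").open() as fh:
            for row in csv.DictReader(fh):
                conversions[(row["from_unit"], row["to_unit"])] = row["formula_id"]
        return cls(mappings, conversions)

    def map_code(self, system: str, code: str) -> Optional[ConceptMapping]:
        """Look up a (system, code) pair; ``None`` signals "not mapped"."""
        return self._by_code.get((system, code))

    def mapping_for_feature(self, feature_name: str) -> Optional[ConceptMapping]:
        return self._by_feature.get(feature_name)

    def normalize_unit(self, value: float, unit: str, canonical_unit: str) -> float:
        """Express ``value`` in the canonical unit.

        Identity when the units already agree; otherwise the registered formula.
        Idempotent by construction: normalize(normalize(v)) == normalize(v).
        """
        if unit == canonical_unit:
            return float(value)
        formula_id = self._conversions.get((unit, canonical_unit))
        if formula_id is None:
            raise UnitConversionError(unit, canonical_unit)
        return float(_FORMULAS[formula_id](value))


_DEFAULT_VOCABULARY: Optional[Vocabulary] = None


def default_vocabulary() -> Vocabulary:
    global _DEFAULT_VOCABULARY
    if _DEFAULT_VOCABULARY is None:
        _DEFAULT_VOCABULARY = Vocabulary.bundled()
    return _DEFAULT_VOCABULARY


def map_code(system: str, code: str) -> Optional[ConceptMapping]:
    """Module-level convenience over the bundled vocabulary."""
    return default_vocabulary().map_code(system, code)


def normalize_unit(value: float, unit: str, canonical_unit: str) -> float:
    return default_vocabulary().normalize_unit(value, unit, canonical_unit)


def _in_window(t: Optional[datetime], reference_time: datetime, lookback: timedelta) -> bool:
    if t is None or isinstance(t, str):
        return False
    return reference_time - lookback <= t <= reference_time


def _matches_order_feature(name: str, resource) -> bool:
    if name == "antibiotics_ordered":
        return (
            isinstance(resource, MedicationRequestResource)
            and resource.medication_code.code.startswith(ANTIBIOTIC_ATC_PREFIXES)
        )
    if name == "vasopressor_ordered":
        return (
            isinstance(resource, MedicationRequestResource)
            and resource.medication_code.code.startswith(VASOPRESSOR_ATC_PREFIXES)
        )
    if name == "blood_culture_ordered":
        return (
            isinstance(resource, ServiceRequestResource)
            and resource.procedure_code.code in BLOOD_CULTURE_CODES
        )
    return False


def extract_features(
    bundle: FhirBundle,
    descriptor: EngineDescriptor,
    reference_time: datetime,
    vocabulary: Optional[Vocabulary] = None,
) -> FeatureRecord:
    """Build the :class:`FeatureRecord` the engine described by ``descriptor`` needs.

    Selection rules, applied deterministically:

    * observation features: the latest ``final`` Observation whose code maps to
      the feature, inside ``[reference_time - lookback, reference_time]``;
      ties in observed time are broken by bundle entry order (later entry wins);
      values are unit-normalized to the canonical unit;
    * order features (``*_ordered``): boolean, true iff a matching
      active/completed request is in-window; absent orders are ``False``, not
      missing;
    * demographic features (age, sex, arrival_mode, encounter_class) come from
      the Patient/Encounter resources;
    * ``gcs`` falls back to the coarse responsiveness scale (AVPU) via
      :data:`AVPU_TO_GCS` when no numeric Glasgow Coma Scale observation is
      in-window.
    """
    vocab = vocabulary or default_vocabulary()
    lookback = timedelta(hours=descriptor.lookback_hours)

    patients = [e for e in bundle.entries if isinstance(e, PatientResource)]
    encounters = [e for e in bundle.entries if isinstance(e, EncounterResource)]
    patient = patients[0] if patients else None
    encounter = encounters[0] if encounters else None

    record = FeatureRecord(
        patient_id=patient.resource_id if patient else "",
        reference_time=reference_time,
    )

    # Latest in-window final observation per mapped feature name.
    latest: dict[str, tuple[datetime, ObservationResource]] = {}
    for res in bundle.entries:
        if not isinstance(res, ObservationResource):
            continue
        if res.status != "final":
            continue
        mapping = vocab.map_code(res.code.system, res.code.code)
        if mapping is None:
            record.log.append(f"unmapped code {res.code.system}|{res.code.code} ({res.resource_id})")
            continue
        if not _in_window(res.effective_time, reference_time, lookback):
            continue
        prev = latest.get(mapping.feature_name)
        # >= : equal timestamps resolved by entry order, later entry wins
        if prev is None or res.effective_time >= prev[0]:
            latest[mapping.feature_name] = (res.effective_time, res)

    def observation_value(name: str) -> Optional[FeatureValue]:
        hit = latest.get(name)
        if hit is None:
            return None
        t, obs = hit
        mapping = vocab.mapping_for_feature(name)
        if obs.value_quantity is not None:
            try:
                value = vocab.normalize_unit(
                    obs.value_quantity.value, obs.value_quantity.unit, mapping.canonical_unit
                )
            except UnitConversionError as exc:
                record.log.append(f"{name}: {exc}")
                return None
            return FeatureValue(value=value, unit=mapping.canonical_unit, observed_time=t, provenance=obs.resource_id)
        return FeatureValue(value=obs.value_coded.code, unit=mapping.canonical_unit, observed_time=t, provenance=obs.resource_id)

    for spec in descriptor.required_features:
        fv: Optional[FeatureValue] = None
        if spec.kind == "order":
            ordered = False
            prov = ""
            for res in bundle.entries:
                if not _matches_order_feature(spec.name, res):
                    continue
                if res.status not in ("active", "completed"):
                    continue
                if _in_window(res.authored_time, reference_time, lookback):
                    ordered = True
                    prov = res.resource_id
                    break
            fv = FeatureValue(value=ordered, unit="", provenance=prov)
        elif spec.kind == "demographic":
            fv = _demographic_value(spec.name, patient, encounter, reference_time)
        else:  # observation / coded
            fv = observation_value(spec.name)
            if fv is None and spec.name == "gcs":
                avpu = observation_value("mental_status_avpu")
                if avpu is not None and avpu.value in AVPU_TO_GCS:
                    fv = FeatureValue(
                        value=float(AVPU_TO_GCS[avpu.value]),
                        unit=spec.unit,
                        observed_time=avpu.observed_time,
                        provenance=avpu.provenance,
                    )
                    record.log.append(f"gcs derived from AVPU {avpu.value!r}")

        if fv is None:
            if spec.required:
                record.missing.add(spec.name)
                record.log.append(f"required feature {spec.name!r} missing")
        else:
            record.features[spec.name] = fv
    return record


def _demographic_value(
    name: str,
    patient: Optional[PatientResource],
    encounter: Optional[EncounterResource],
    reference_time: datetime,
) -> Optional[FeatureValue]:
    if name == "age":
        if patient is None or patient.birth_date is None:
            return None
        bd = patient.birth_date
        ref = reference_time.date()
        age = ref.year - bd.year - ((ref.month, ref.day) < (bd.month, bd.day))
        return FeatureValue(value=float(age), unit="a", provenance=patient.resource_id)
    if name == "sex":
        if patient is None or patient.administrative_sex is None:
            return None
        return FeatureValue(value=patient.administrative_sex, unit="", provenance=patient.resource_id)
    if name == "arrival_mode":
        if encounter is None or encounter.arrival_mode is None:
            return None
        return FeatureValue(value=encounter.arrival_mode, unit="", provenance=encounter.resource_id)
    if name == "encounter_class":
        if encounter is None:
            return None
        return FeatureValue(value=encounter.class_code, unit="", provenance=encounter.resource_id)
    return None
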