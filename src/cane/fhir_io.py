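"""Read, validate, and write the FHIR R4 resource subset exchanged with the platform.

The platform speaks FHIR R4 JSON, exchanged as ``Bundle`` documents of type
``collection``.  Five resource types are modelled in full — Patient, Encounter,
Observation, MedicationRequest, ServiceRequest — which together carry the
demographics, vitals, labs, and orders the reasoning engines consume.  Any other
resource type is carried opaquely (raw JSON preserved, round-trippable) and
flagged, never dropped: real-world bundles degrade gracefully.

Timestamps are ISO-8601; naive timestamps are interpreted as UTC.
"""

from __future__ import annotations

import json
from datetime import date, datetime, timezone
from enum import Enum
from typing import Any, Optional, Union

from pydantic import BaseModel, ConfigDict

SUPPORTED_RESOURCE_TYPES = frozenset(
    {"Patient", "Encounter", "Observation", "MedicationRequest", "ServiceRequest"}
)

# FHIR v3-ActCode encounter classes <-> platform vocabulary
_ENCOUNTER_CLASS_FROM_FHIR = {"EMER": "emergency", "IMP": "inpatient", "AMB": "outpatient"}
_ENCOUNTER_CLASS_TO_FHIR = {v: k for k, v in _ENCOUNTER_CLASS_FROM_FHIR.items()}


class BundleParseError(ValueError):
    """Malformed JSON or a document that is not a collection Bundle."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


class BundleValidationError(ValueError):
    """A supported resource violates a structural invariant at parse time."""

    def __init__(self, issues: list["ValidationIssue"]):
        self.issues = issues
        super().__init__("; ".join(str(i) for i in issues))


class ValidationIssue(BaseModel):
    """One invariant violation: which resource, which field, which rule."""

    resource_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.resource_id}].{self.field}: {self.rule}"


def parse_instant(text: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive values are taken as UTC."""
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


def _format_instant(dt: datetime) -> str:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.isoformat()


class CodedValue(BaseModel):
    model_config = ConfigDict(frozen=True)
    system: str
    code: str
    display: Optional[str] = None


class Quantity(BaseModel):
    model_config = ConfigDict(frozen=True)
    value: float
    unit: str


class PatientResource(BaseModel):
    resource_type: str = "Patient"
    resource_id: str
    birth_date: Optional[date] = None
    administrative_sex: Optional[str] = None  # male | female | other | unknown


class EncounterResource(BaseModel):
    resource_type: str = "Encounter"
    resource_id: str
    subject_ref: Optional[str] = None
    class_code: str  # emergency | inpatient | outpatient
    start_time: Optional[Union[datetime, str]] = None
    arrival_mode: Optional[str] = None  # coded admit source, e.g. "amb"


class ObservationResource(BaseModel):
    resource_type: str = "Observation"
    resource_id: str
    subject_ref: Optional[str] = None
    code: CodedValue
    value_quantity: Optional[Quantity] = None
    value_coded: Optional[CodedValue] = None
    # str when the incoming timestamp could not be parsed; validate_bundle flags it
    effective_time: Optional[Union[datetime, str]] = None
    status: str = "final"  # final | preliminary


class MedicationRequestResource(BaseModel):
    resource_type: str = "MedicationRequest"
    resource_id: str
    subject_ref: Optional[str] = None
    medication_code: CodedValue
    intent: str = "order"
    authored_time: Optional[Union[datetime, str]] = None
    status: str = "active"  # active | completed


class ServiceRequestResource(BaseModel):
    resource_type: str = "ServiceRequest"
    resource_id: str
    subject_ref: Optional[str] = None
    procedure_code: CodedValue
    authored_time: Optional[Union[datetime, str]] = None
    status: str = "active"  # active | completed


class OpaqueResource(BaseModel):
    """An unsupported resource type, carried verbatim and flagged."""

    resource_type: str
    resource_id: str
    raw: dict


FhirResource = Union[
    PatientResource,
    EncounterResource,
    ObservationResource,
    MedicationRequestResource,
    ServiceRequestResource,
    OpaqueResource,
]


class FhirBundle(BaseModel):
    bundle_id: str
    bundle_type: str = "collection"
    entries: list[FhirResource] = []

    @property
    def opaque_entries(self) -> list[OpaqueResource]:
        return [e for e in self.entries if isinstance(e, OpaqueResource)]

    def resources(self, resource_type: str) -> list[FhirResource]:
        return [e for e in self.entries if e.resource_type == resource_type]


# ---------------------------------------------------------------------------
# parsing


def _coding(concept: Optional[dict]) -> Optional[CodedValue]:
    if not concept:
        return None
    codings = concept.get("coding") or []
    if not codings:
        return None
    c = codings[0]
    return CodedValue(system=c.get("system", ""), code=c.get("code", ""), display=c.get("display"))


def _maybe_instant(text: Optional[str]) -> Optional[Union[datetime, str]]:
    if text is None:
        return None
    try:
        return parse_instant(text)
    except ValueError:
        return text  # kept raw; validate_bundle reports it


def _subject(raw: dict) -> Optional[str]:
    ref = (raw.get("subject") or {}).get("reference")
    if ref and ref.startswith("Patient/"):
        return ref.split("/", 1)[1]
    return ref


def _require(raw: dict, rid: str, field: str, issues: list[ValidationIssue]) -> Any:
    value = raw.get(field)
    if value is None:
        issues.append(ValidationIssue(resource_id=rid, field=field, rule="required field absent"))
    return value


def _parse_resource(raw: dict) -> FhirResource:
    rtype = raw.get("resourceType", "")
    rid = raw.get("id", "")
    issues: list[ValidationIssue] = []

    if rtype == "Patient":
        bd = raw.get("birthDate")
        resource: FhirResource = PatientResource(
            resource_id=rid,
            birth_date=date.fromisoformat(bd) if bd else None,
            administrative_sex=raw.get("gender"),
        )
    elif rtype == "Encounter":
        klass = (raw.get("class") or {}).get("code", "")
        if klass not in _ENCOUNTER_CLASS_FROM_FHIR:
            issues.append(
                ValidationIssue(resource_id=rid, field="class", rule=f"unknown encounter class {klass!r}")
            )
            raise BundleValidationError(issues)
        admit = ((raw.get("hospitalization") or {}).get("admitSource") or {})
        arrival = None
        if admit.get("coding"):
            arrival = admit["coding"][0].get("code")
        resource = EncounterResource(
            resource_id=rid,
            subject_ref=_subject(raw),
            class_code=_ENCOUNTER_CLASS_FROM_FHIR[klass],
            start_time=_maybe_instant((raw.get("period") or {}).get("start")),
            arrival_mode=arrival,
        )
    elif rtype == "Observation":
        code = _coding(_require(raw, rid, "code", issues))
        status = raw.get("status", "final")
        if status not in ("final", "preliminary"):
            issues.append(ValidationIssue(resource_id=rid, field="status", rule=f"unknown status {status!r}"))
        vq = raw.get("valueQuantity")
        vc = _coding(raw.get("valueCodeableConcept"))
        if (vq is None) == (vc is None):
            issues.append(
                ValidationIssue(
                    resource_id=rid,
                    field="value",
                    rule="exactly one of valueQuantity / valueCodeableConcept must be present",
                )
            )
        if issues:
            raise BundleValidationError(issues)
        resource = ObservationResource(
            resource_id=rid,
            subject_ref=_subject(raw),
            code=code,
            value_quantity=Quantity(value=vq["value"], unit=vq.get("unit", "")) if vq else None,
            value_coded=vc,
            effective_time=_maybe_instant(raw.get("effectiveDateTime")),
            status=status,
        )
    elif rtype == "MedicationRequest":
        code = _coding(raw.get("medicationCodeableConcept"))
        if code is None or not code.code:
            issues.append(
                ValidationIssue(resource_id=rid, field="medicationCodeableConcept", rule="medication code empty")
            )
            raise BundleValidationError(issues)
        status = raw.get("status", "active")
        if status not in ("active", "completed"):
            issues.append(ValidationIssue(resource_id=rid, field="status", rule=f"unknown status {status!r}"))
            raise BundleValidationError(issues)
        resource = MedicationRequestResource(
            resource_id=rid,
            subject_ref=_subject(raw),
            medication_code=code,
            intent=raw.get("intent", "order"),
            authored_time=_maybe_instant(raw.get("authoredOn")),
            status=status,
        )
    elif rtype == "ServiceRequest":
        code = _coding(raw.get("code"))
        if code is None or not code.code:
            issues.append(ValidationIssue(resource_id=rid, field="code", rule="procedure code empty"))
            raise BundleValidationError(issues)
        status = raw.get("status", "active")
        if status not in ("active", "completed"):
            issues.append(ValidationIssue(resource_id=rid, field="status", rule=f"unknown status {status!r}"))
            raise BundleValidationError(issues)
        resource = ServiceRequestResource(
            resource_id=rid,
            subject_ref=_subject(raw),
            procedure_code=code,
            authored_time=_maybe_instant(raw.get("authoredOn")),
            status=status,
        )
    else:
        resource = OpaqueResource(resource_type=rtype, resource_id=rid, raw=raw)
    if issues:
        raise BundleValidationError(issues)
    return resource


def parse_bundle(text: str) -> FhirBundle:
    """Parse a FHIR R4 JSON collection Bundle into a typed :class:`FhirBundle`.

    Unsupported resource types become :class:`OpaqueResource` entries (flagged,
    retained).  Malformed JSON raises :class:`BundleParseError` with the byte
    offset; a supported resource violating a structural invariant raises
    :class:`BundleValidationError` naming the resource id and field.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BundleParseError(f"malformed JSON: {exc.msg}", offset=exc.pos) from exc
    if not isinstance(doc, dict) or doc.get("resourceType") != "Bundle":
        raise BundleParseError("document is not a FHIR Bundle")
    btype = doc.get("type", "collection")
    if btype != "collection":
        raise BundleParseError(f"unsupported bundle type {btype!r}; only 'collection' is exchanged")
    entries = []
    for entry in doc.get("entry") or []:
        raw = entry.get("resource")
        if raw is None:
            continue
        entries.append(_parse_resource(raw))
    return FhirBundle(bundle_id=doc.get("id", ""), bundle_type=btype, entries=entries)


# ---------------------------------------------------------------------------
# serialization


def _serialize_time(value: Optional[Union[datetime, str]]) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, str):
        return value
    return _format_instant(value)


def _concept(code: CodedValue) -> dict:
    coding: dict = {"system": code.system, "code": code.code}
    if code.display is not None:
        coding["display"] = code.display
    return {"coding": [coding]}


def _serialize_resource(res: FhirResource) -> dict:
    if isinstance(res, OpaqueResource):
        return res.raw
    if isinstance(res, PatientResource):
        raw = {"resourceType": "Patient", "id": res.resource_id}
        if res.birth_date is not None:
            raw["birthDate"] = res.birth_date.isoformat()
        if res.administrative_sex is not None:
            raw["gender"] = res.administrative_sex
        return raw
    if isinstance(res, EncounterResource):
        raw = {
            "resourceType": "Encounter",
            "id": res.resource_id,
            "class": {
                "system": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
                "code": _ENCOUNTER_CLASS_TO_FHIR[res.class_code],
            },
        }
        if res.subject_ref:
            raw["subject"] = {"reference": f"Patient/{res.subject_ref}"}
        if res.start_time is not None:
            raw["period"] = {"start": _serialize_time(res.start_time)}
        if res.arrival_mode is not None:
            raw["hospitalization"] = {"admitSource": {"coding": [{"code": res.arrival_mode}]}}
        return raw
    if isinstance(res, ObservationResource):
        raw = {
            "resourceType": "Observation",
            "id": res.resource_id,
            "status": res.status,
            "code": _concept(res.code),
        }
        if res.subject_ref:
            raw["subject"] = {"reference": f"Patient/{res.subject_ref}"}
        if res.value_quantity is not None:
            raw["valueQuantity"] = {"value": res.value_quantity.value, "unit": res.value_quantity.unit}
        if res.value_coded is not None:
            raw["valueCodeableConcept"] = _concept(res.value_coded)
        if res.effective_time is not None:
            raw["effectiveDateTime"] = _serialize_time(res.effective_time)
        return raw
    if isinstance(res, MedicationRequestResource):
        raw = {
            "resourceType": "MedicationRequest",
            "id": res.resource_id,
            "status": res.status,
            "intent": res.intent,
            "medicationCodeableConcept": _concept(res.medication_code),
        }
        if res.subject_ref:
            raw["subject"] = {"reference": f"Patient/{res.subject_ref}"}
        if res.authored_time is not None:
            raw["authoredOn"] = _serialize_time(res.authored_time)
        return raw
    if isinstance(res, ServiceRequestResource):
        raw = {
            "resourceType": "ServiceRequest",
            "id": res.resource_id,
            "status": res.status,
            "code": _concept(res.procedure_code),
        }
        if res.subject_ref:
            raw["subject"] = {"reference": f"Patient/{res.subject_ref}"}
        if res.authored_time is not None:
            raw["authoredOn"] = _serialize_time(res.authored_time)
        return raw
    raise TypeError(f"unknown resource {type(res)!r}")  # pragma: no cover


def serialize_bundle(bundle: FhirBundle, indent: Optional[int] = None) -> str:
    """Inverse of :func:`parse_bundle`: ``parse_bundle(serialize_bundle(b)) == b``."""
    doc = {
        "resourceType": "Bundle",
        "id": bundle.bundle_id,
        "type": bundle.bundle_type,
        "entry": [{"resource": _serialize_resource(r)} for r in bundle.entries],
    }
    return json.dumps(doc, indent=indent)


# ---------------------------------------------------------------------------
# validation


def validate_bundle(bundle: FhirBundle) -> list[ValidationIssue]:
    """Collect invariant violations as data.  Empty list iff the bundle is valid.

    Pure: repeated calls on the same bundle yield identical issue lists.
    """
    issues: list[ValidationIssue] = []
    seen_ids: set[str] = set()
    encounter_starts: list[datetime] = []
    patients: list[PatientResource] = []

    for res in bundle.entries:
        if res.resource_id in seen_ids:
            issues.append(
                ValidationIssue(resource_id=res.resource_id, field="id", rule="duplicate entry id within bundle")
            )
        else:
            seen_ids.add(res.resource_id)

        if isinstance(res, ObservationResource):
            if (res.value_quantity is None) == (res.value_coded is None):
                issues.append(
                    ValidationIssue(
                        resource_id=res.resource_id,
                        field="value",
                        rule="exactly one of value_quantity / value_coded must be present",
                    )
                )
            if isinstance(res.effective_time, str):
                issues.append(
                    ValidationIssue(
                        resource_id=res.resource_id,
                        field="effective_time",
                        rule=f"timestamp not ISO-8601: {res.effective_time!r}",
                    )
                )
        elif isinstance(res, (MedicationRequestResource, ServiceRequestResource)):
            code = res.medication_code if isinstance(res, MedicationRequestResource) else res.procedure_code
            field = "medication_code" if isinstance(res, MedicationRequestResource) else "procedure_code"
            if not code.code:
                issues.append(ValidationIssue(resource_id=res.resource_id, field=field, rule="code empty"))
            if isinstance(res.authored_time, str):
                issues.append(
                    ValidationIssue(
                        resource_id=res.resource_id,
                        field="authored_time",
                        rule=f"timestamp not ISO-8601: {res.authored_time!r}",
                    )
                )
        elif isinstance(res, EncounterResource):
            if isinstance(res.start_time, str):
                issues.append(
                    ValidationIssue(
                        resource_id=res.resource_id,
                        field="start_time",
                        rule=f"timestamp not ISO-8601: {res.start_time!r}",
                    )
                )
            elif res.start_time is not None:
                encounter_starts.append(res.start_time)
        elif isinstance(res, PatientResource):
            patients.append(res)
        elif isinstance(res, OpaqueResource):
            issues.append(
                ValidationIssue(
                    resource_id=res.resource_id,
                    field="resourceType",
                    rule=f"unsupported resource type {res.resource_type!r} carried opaquely",
                )
            )

    for pat in patients:
        if pat.birth_date is None:
            continue
        for start in encounter_starts:
            if pat.birth_date > start.date():
                issues.append(
                    ValidationIssue(
                        resource_id=pat.resource_id,
                        field="birth_date",
                        rule="birth_date after encounter start_time",
                    )
                )
    return issues
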