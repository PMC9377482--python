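"""Population-level summary reports over an OMOP-CDM-like local store.

The integration center of the platform: each institution resolves a cohort
against its own relational store (person / visit / measurement / drug_exposure /
condition / death tables), aggregates to labelled cells (per-drug usage,
outcomes), suppresses small cells below a threshold k, and exchanges only the
resulting :class:`SummaryReport` with peers.  Raw person-level rows never cross
an institution boundary; a schema validator rejects any inbound payload that
carries person-level fields.

Suppression policy: a cell with 0 < count < k is suppressed (count and rate
withheld in the serialized form).  Zero counts are reported — revealing absence
is an accepted, documented threat-model choice.  Merged reports are
re-suppressed after summation so the merged report honors the same k.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import pandas as pd

DEFAULT_K = 10
SCHEMA_VERSION = "1"

TABLE_COLUMNS = {
    "person": ["person_id", "birth_date", "sex_concept"],
    "visit": ["visit_id", "person_id", "visit_class", "start", "end"],
    "measurement": ["person_id", "concept_id", "value", "unit", "time"],
    "drug_exposure": ["person_id", "drug_concept_id", "time"],
    "condition": ["person_id", "condition_concept_id", "time"],
    "death": ["person_id", "time"],
}

# field names that must never appear in an exchanged summary payload
PERSON_LEVEL_FIELDS = frozenset(
    {"person_id", "person_ids", "birth_date", "visit_id", "measurement_time", "death_time"}
)


class StoreIntegrityError(ValueError):
    """A foreign key fails to resolve or a concept id is non-positive."""


class ReportSchemaError(ValueError):
    """An exchanged payload violates the summary-report schema (privacy gate)."""


class MergeError(ValueError):
    """Reports with mismatched cohort names or k thresholds cannot be merged."""


@dataclass
class LocalStore:
    """Minimal OMOP-like relational store held as pandas tables."""

    person: pd.DataFrame
    visit: pd.DataFrame
    measurement: pd.DataFrame
    drug_exposure: pd.DataFrame
    condition: pd.DataFrame
    death: pd.DataFrame

    @classmethod
    def empty(cls) -> "LocalStore":
        return cls(**{name: pd.DataFrame(columns=cols) for name, cols in TABLE_COLUMNS.items()})

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "LocalStore":
        """Read one CSV per table from a directory; validates integrity."""
        directory = Path(directory)
        tables = {}
        for name, cols in TABLE_COLUMNS.items():
            path = directory / f"{name}.csv"
            tables[name] = pd.read_csv(path) if path.exists() else pd.DataFrame(columns=cols)
        store = cls(**tables)
        store.validate()
        return store

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in TABLE_COLUMNS:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    def validate(self) -> None:
        """All person_id foreign keys resolve; concept ids are positive."""
        persons = set(self.person["person_id"])
        for name in ("visit", "measurement", "drug_exposure", "condition", "death"):
            table = getattr(self, name)
            if len(table) == 0:
                continue
            unresolved = set(table["person_id"]) - persons
            if unresolved:
                raise StoreIntegrityError(f"{name}: unresolved person_id foreign keys {sorted(unresolved)[:5]}")
        for name, col in (
            ("measurement", "concept_id"),
            ("drug_exposure", "drug_concept_id"),
            ("condition", "condition_concept_id"),
        ):
            table = getattr(self, name)
            if len(table) and (table[col] <= 0).any():
                raise StoreIntegrityError(f"{name}.{col}: non-positive concept id")


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion rules and stratifiers defining the population to summarize."""

    name: str
    condition_concepts: tuple[int, ...]  # inclusion: any of these condition concept ids
    visit_classes: tuple[str, ...] = ()  # optional restriction, e.g. ("emergency",)
    time_window: Optional[tuple[str, str]] = None  # ISO dates, inclusive
    stratify_by_drug: bool = True  # one cell per drug concept among cohort members
    drug_label_prefix: str = "drug"

    def __post_init__(self):
        if not self.condition_concepts:
            raise ValueError("a cohort spec needs at least one inclusion rule")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "condition_concepts": list(self.condition_concepts),
            "visit_classes": list(self.visit_classes),
            "time_window": list(self.time_window) if self.time_window else None,
            "stratify_by_drug": self.stratify_by_drug,
            "drug_label_prefix": self.drug_label_prefix,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortSpec":
        return cls(
            name=doc["name"],
            condition_concepts=tuple(doc["condition_concepts"]),
            visit_classes=tuple(doc.get("visit_classes") or ()),
            time_window=tuple(doc["time_window"]) if doc.get("time_window") else None,
            stratify_by_drug=doc.get("stratify_by_drug", True),
            drug_label_prefix=doc.get("drug_label_prefix", "drug"),
        )


@dataclass
class SummaryCell:
    label: str
    count: Optional[int]  # None once suppressed
    rate: Optional[float]  # count / n_total, None once suppressed
    suppressed: bool = False
    partially_suppressed: bool = False  # merged from sites where the cell was suppressed
    contributing_sites: int = 1


@dataclass
class SummaryReport:
    """The only object that crosses institution boundaries."""

    institution_id: str
    cohort_name: str
    n_total: int
    cells: list[SummaryCell]
    k_threshold: int
    generated_time: str = ""
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        if not self.generated_time:
            self.generated_time = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def cell(self, label: str) -> Optional[SummaryCell]:
        for c in self.cells:
            if c.label == label:
                return c
        return None

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "institution_id": self.institution_id,
            "cohort_name": self.cohort_name,
            "n_total": self.n_total,
            "k_threshold": self.k_threshold,
            "generated_time": self.generated_time,
            "cells": [
                {
                    "label": c.label,
                    # suppressed cells carry no count/rate on the wire
                    "count": None if c.suppressed else c.count,
                    "rate": None if c.suppressed else c.rate,
                    "suppressed": c.suppressed,
                    "partially_suppressed": c.partially_suppressed,
                    "contributing_sites": c.contributing_sites,
                }
                for c in self.cells
            ],
        }

    def to_json(self, indent: Optional[int] = None) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, doc: dict) -> "SummaryReport":
        validate_report_payload(doc)
        cells = [
            SummaryCell(
                label=c["label"],
                count=c.get("count"),
                rate=c.get("rate"),
                suppressed=c.get("suppressed", False),
                partially_suppressed=c.get("partially_suppressed", False),
                contributing_sites=c.get("contributing_sites", 1),
            )
            for c in doc.get("cells", [])
        ]
        return cls(
            institution_id=doc["institution_id"],
            cohort_name=doc["cohort_name"],
            n_total=doc["n_total"],
            cells=cells,
            k_threshold=doc["k_threshold"],
            generated_time=doc.get("generated_time", ""),
            schema_version=doc.get("schema_version", SCHEMA_VERSION),
        )


def validate_report_payload(doc: object) -> None:
    """Privacy gate: reject any payload carrying person-level fields, recursively."""

    def walk(node, path="$"):
        if isinstance(node, dict):
            for key, value in node.items():
                if key in PERSON_LEVEL_FIELDS:
                    raise ReportSchemaError(f"person-level field {key!r} at {path} in summary payload")
                walk(value, f"{path}.{key}")
        elif isinstance(node, list):
            for i, item in enumerate(node):
                walk(item, f"{path}[{i}]")

    walk(doc)


# ---------------------------------------------------------------------------
# building


def resolve_cohort(store: LocalStore, spec: CohortSpec) -> set:
    """Person ids satisfying the inclusion rules."""
    cond = store.condition
    if len(cond) == 0:
        return set()
    mask = cond["condition_concept_id"].isin(spec.condition_concepts)
    if spec.time_window is not None:
        lo, hi = spec.time_window
        times = pd.to_datetime(cond["time"], utc=True, format="ISO8601")
        mask &= (times >= pd.Timestamp(lo, tz="UTC")) & (times <= pd.Timestamp(hi, tz="UTC"))
    members = set(cond.loc[mask, "person_id"])
    if spec.visit_classes:
        visited = set(store.visit.loc[store.visit["visit_class"].isin(spec.visit_classes), "person_id"])
        members &= visited
    return members


def build_summary(
    store: LocalStore, spec: CohortSpec, k: int = DEFAULT_K, institution_id: str = "local"
) -> SummaryReport:
    """Resolve the cohort and aggregate it into a suppressed summary report.

    One cell per drug concept observed among cohort members (when
    ``spec.stratify_by_drug``), plus outcome cells for in-hospital death and
    hospitalization.  An empty cohort yields ``n_total = 0`` and no cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    store.validate()
    members = resolve_cohort(store, spec)
    n_total = len(members)
    if n_total == 0:
        return SummaryReport(
            institution_id=institution_id, cohort_name=spec.name, n_total=0, cells=[], k_threshold=k
        )

    cells: list[SummaryCell] = []
    if spec.stratify_by_drug and len(store.drug_exposure):
        exposed = store.drug_exposure[store.drug_exposure["person_id"].isin(members)]
        per_drug = exposed.groupby("drug_concept_id")["person_id"].nunique().sort_index()
        for concept_id, count in per_drug.items():
            cells.append(
                SummaryCell(
                    label=f"{spec.drug_label_prefix}:{concept_id}",
                    count=int(count),
                    rate=count / n_total,
                )
            )

    deaths = len(set(store.death["person_id"]) & members) if len(store.death) else 0
    cells.append(SummaryCell(label="outcome:in_hospital_death", count=deaths, rate=deaths / n_total))
    if len(store.visit):
        admitted = set(store.visit.loc[store.visit["visit_class"] == "inpatient", "person_id"]) & members
    else:
        admitted = set()
    cells.append(
        SummaryCell(label="outcome:hospitalization", count=len(admitted), rate=len(admitted) / n_total)
    )

    report = SummaryReport(
        institution_id=institution_id, cohort_name=spec.name, n_total=n_total, cells=cells, k_threshold=k
    )
    return suppress_small_cells(report, k)


def suppress_small_cells(report: SummaryReport, k: int) -> SummaryReport:
    """Mark every cell with 0 < count < k suppressed; idempotent.

    Zero counts stay visible (absence is non-disclosive under the default
    threat model).  Already-suppressed cells are left untouched.
    """
    cells = []
    for c in report.cells:
        if c.suppressed or (c.count is not None and 0 < c.count < k):
            cells.append(replace(c, count=None, rate=None, suppressed=True))
        else:
            cells.append(replace(c))
    return replace(report, cells=cells, k_threshold=k)


def merge_summaries(reports: list[SummaryReport]) -> SummaryReport:
    """Combine per-site reports into one federation-level report.

    Counts are summed over the sites where the cell is unsuppressed; a label
    suppressed anywhere is marked ``partially_suppressed`` with the count of
    sites that did contribute.  ``n_total`` sums across sites and the merged
    cells are re-suppressed at the shared k.
    """
    if not reports:
        raise MergeError("nothing to merge")
    first = reports[0]
    for r in reports[1:]:
        if r.cohort_name != first.cohort_name:
            raise MergeError(f"cohort name mismatch: {r.cohort_name!r} vs {first.cohort_name!r}")
        if r.k_threshold != first.k_threshold:
            raise MergeError(f"k mismatch: {r.k_threshold} vs {first.k_threshold}")

    n_total = sum(r.n_total for r in reports)
    labels: list[str] = []
    for r in reports:
        for c in r.cells:
            if c.label not in labels:
                labels.append(c.label)

    merged_cells = []
    for label in labels:
        total = 0
        contributing = 0
        partially = False
        for r in reports:
            c = r.cell(label)
            if c is None:
                continue
            if c.suppressed:
                partially = True
            else:
                total += c.count or 0
                contributing += c.contributing_sites
            partially = partially or c.partially_suppressed
        merged_cells.append(
            SummaryCell(
                label=label,
                count=total,
                rate=total / n_total if n_total else 0.0,
                partially_suppressed=partially,
                contributing_sites=contributing,
            )
        )

    merged = SummaryReport(
        institution_id="+".join(r.institution_id for r in reports),
        cohort_name=first.cohort_name,
        n_total=n_total,
        cells=merged_cells,
        k_threshold=first.k_threshold,
    )
    return suppress_small_cells(merged, first.k_threshold)


# ---------------------------------------------------------------------------
# peer transport


@dataclass
class PeerUnavailable:
    """Typed degradation marker: the CDS response renders without this peer."""

    endpoint: str
    reason: str


class LocalPeer:
    """In-process peer: an institution's store behind the request contract."""

    def __init__(self, store: LocalStore, institution_id: str, k: int = DEFAULT_K):
        self._store = store
        self.institution_id = institution_id
        self._k = k
        self.endpoint = f"local://{institution_id}"

    def request(self, spec: CohortSpec) -> dict:
        return build_summary(self._store, spec, k=self._k, institution_id=self.institution_id).to_dict()


class HttpPeer:
    """Remote peer over HTTP: POST the cohort spec, receive a summary payload."""

    def __init__(self, endpoint: str, timeout: float = 5.0):
        self.endpoint = endpoint
        self.timeout = timeout

    def request(self, spec: CohortSpec) -> dict:
        body = json.dumps({"cohort_spec": spec.to_dict()}).encode()
        req = urllib.request.Request(
            self.endpoint, data=body, headers={"Content-Type": "application/json"}, method="POST"
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read().decode())


def request_summary(peer, spec: CohortSpec) -> Union[SummaryReport, PeerUnavailable]:
    """Ask a peer for its summary of ``spec``; degrade, never raise, on failure.

    The request carries only the cohort spec.  The response passes the privacy
    gate (:func:`validate_report_payload`) before being typed; a payload with
    person-level fields is treated as unavailable, with the violation recorded.
    """
    endpoint = getattr(peer, "endpoint", "unknown")
    try:
        payload = peer.request(spec)
        return SummaryReport.from_dict(payload)
    except ReportSchemaError as exc:
        return PeerUnavailable(endpoint=endpoint, reason=f"privacy gate rejected response: {exc}")
    except (urllib.error.URLError, TimeoutError, OSError, KeyError, ValueError) as exc:
        return PeerUnavailable(endpoint=endpoint, reason=str(exc))
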