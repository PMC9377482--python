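"""Request/response orchestration: preprocessing -> reasoning engine -> integration.

A CDS request names a registered engine and carries a FHIR bundle plus a
reference time.  The service extracts the engine's declared features, runs the
engine, optionally gathers peer summary reports, and composes a structured
display payload.  Engines are in-process plugins: a descriptor (what features
they need) plus a callable ``FeatureRecord -> result``.

Failures are typed response documents, never transport faults: an unknown
engine yields a not-found response, an engine exception an error response, and
an unreachable peer an unavailability marker inside an otherwise complete
response — the EHR side can always render something.

A thin stdlib HTTP server (`serve`) exposes the same operations on the wire:
``POST /cds/{engine_name}``, ``GET /engines``, and ``POST /summary`` (the peer
endpoint serving this institution's population-level summaries).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Callable, Optional, Sequence, Union

from .federated_summary import (
    DEFAULT_K,
    CohortSpec,
    LocalStore,
    PeerUnavailable,
    SummaryReport,
    build_summary,
    request_summary,
)
from .fhir_io import FhirBundle, parse_bundle, parse_instant, serialize_bundle
from .sepstreat_engine import SepsisAssessment, SEPSTREAT_DESCRIPTOR
from .sepstreat_engine import run_engine as run_sepstreat
from .triage_engine import TRIAGE_DESCRIPTOR, TriageModel, TriagePrediction, build_engine
from .vocabulary_preprocessing import EngineDescriptor, FeatureRecord, extract_features

Engine = Callable[[FeatureRecord], Any]


class DuplicateEngineError(ValueError):
    pass


class UnknownEngineError(KeyError):
    pass


class EngineRegistry:
    """Resolvable (name, version) -> (descriptor, engine callable)."""

    def __init__(self):
        self._engines: dict[tuple[str, str], tuple[EngineDescriptor, Engine]] = {}

    def register(self, descriptor: EngineDescriptor, engine: Engine) -> None:
        key = (descriptor.engine_name, descriptor.version)
        if key in self._engines:
            raise DuplicateEngineError(f"engine {key} already registered")
        self._engines[key] = (descriptor, engine)

    def get(self, name: str, version: Optional[str] = None) -> tuple[EngineDescriptor, Engine]:
        if version is not None:
            try:
                return self._engines[(name, version)]
            except KeyError:
                raise UnknownEngineError(f"no engine {name!r} version {version!r}") from None
        versions = sorted(v for (n, v) in self._engines if n == name)
        if not versions:
            raise UnknownEngineError(f"no engine {name!r} registered")
        return self._engines[(name, versions[-1])]

    def list_engines(self) -> list[EngineDescriptor]:
        return [d for d, _ in self._engines.values()]

    def __len__(self) -> int:
        return len(self._engines)


def default_registry(triage_model: Optional[TriageModel] = None) -> EngineRegistry:
    """The two shipped engines: the sepsis advisor and the triage predictor.

    Without a supplied model artifact the triage engine is bound to a small
    model trained on a seeded synthetic cohort — enough to exercise the
    pipeline; production deployments pass their own artifact.
    """
    registry = EngineRegistry()
    registry.register(SEPSTREAT_DESCRIPTOR, run_sepstreat)
    if triage_model is None:
        triage_model = _default_triage_model()
    registry.register(TRIAGE_DESCRIPTOR, build_engine(triage_model))
    return registry


_DEFAULT_TRIAGE_MODEL: Optional[TriageModel] = None


def _default_triage_model() -> TriageModel:
    global _DEFAULT_TRIAGE_MODEL
    if _DEFAULT_TRIAGE_MODEL is None:
        from .synthetic_fixtures import CohortProfile, generate_triage_dataset
        from .triage_engine import TriageTrainingConfig, fit_triage_model

        dataset = generate_triage_dataset(CohortProfile(n=2000, seed=20240301))
        _DEFAULT_TRIAGE_MODEL = fit_triage_model(dataset, TriageTrainingConfig(seed=20240301))
    return _DEFAULT_TRIAGE_MODEL


@dataclass
class CdsRequest:
    engine_name: str
    bundle: FhirBundle
    reference_time: datetime
    engine_version: Optional[str] = None
    include_peer_summaries: bool = False
    peers: Sequence[Any] = ()
    cohort_spec: Optional[CohortSpec] = None
    k_threshold: int = DEFAULT_K


@dataclass
class CdsResponse:
    status: str  # ok | error
    engine_name: str
    engine_version: Optional[str] = None
    result: Optional[Union[SepsisAssessment, TriagePrediction, dict]] = None
    preprocessing_log: list[str] = field(default_factory=list)
    missing_features: list[str] = field(default_factory=list)
    peer_summaries: list[Union[SummaryReport, PeerUnavailable]] = field(default_factory=list)
    ui_payload: dict = field(default_factory=dict)
    error: Optional[dict] = None


def _to_plain(obj) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, datetime):
        return obj.isoformat()
    return obj


def result_to_dict(result) -> dict:
    """Engine result as a JSON-ready document."""
    return _to_plain(result)


def compose_ui_payload(result, summaries: Sequence[Union[SummaryReport, PeerUnavailable]], log: Sequence[str] = ()) -> dict:
    """Ordered display sections, all content traceable to its inputs.

    1. headline score(s); 2. recommendation list with completed marks (when the
    result carries one); 3. peer statistics tables (when any peer was asked);
    4. data-quality notes from the preprocessing log.
    """
    sections: list[dict] = []

    if isinstance(result, SepsisAssessment):
        sections.append(
            {
                "section": "headline",
                "scores": {
                    "suspected_infection": result.suspected_infection,
                    "qsofa": result.qsofa.score,
                    "qsofa_positive": result.qsofa.positive,
                    "sofa": result.sofa.total,
                    "sepsis": result.sepsis,
                    "septic_shock": result.septic_shock,
                },
            }
        )
        sections.append(
            {
                "section": "recommendations",
                "items": [
                    {"item_id": i.item_id, "label": i.label, "completed": i.completed}
                    for i in result.recommendations
                ],
            }
        )
    elif isinstance(result, TriagePrediction):
        sections.append(
            {
                "section": "headline",
                "scores": {
                    "probabilities": dict(result.probabilities),
                    "risk_band": result.risk_band,
                    "outcome_bands": dict(result.outcome_bands),
                },
            }
        )
    else:
        sections.append({"section": "headline", "scores": _to_plain(result)})

    if summaries:
        tables = []
        for s in summaries:
            if isinstance(s, PeerUnavailable):
                tables.append({"institution": s.endpoint, "available": False, "reason": s.reason})
            else:
                tables.append(
                    {
                        "institution": s.institution_id,
                        "available": True,
                        "cohort": s.cohort_name,
                        "n_total": s.n_total,
                        "cells": [
                            {"label": c.label, "count": c.count, "rate": c.rate, "suppressed": c.suppressed}
                            for c in s.cells
                        ],
                    }
                )
        sections.append({"section": "peer_statistics", "tables": tables})

    sections.append({"section": "data_quality", "notes": list(log)})
    return {"sections": sections}


def handle_request(request: CdsRequest, registry: EngineRegistry) -> CdsResponse:
    """The deterministic pipeline: extract features -> engine -> peers -> payload."""
    try:
        descriptor, engine = registry.get(request.engine_name, request.engine_version)
    except UnknownEngineError as exc:
        return CdsResponse(
            status="error",
            engine_name=request.engine_name,
            error={"type": "engine_not_found", "message": str(exc)},
        )

    record = extract_features(request.bundle, descriptor, request.reference_time)

    try:
        result = engine(record)
    except Exception as exc:  # engine failure is a typed error, not a fault
        return CdsResponse(
            status="error",
            engine_name=descriptor.engine_name,
            engine_version=descriptor.version,
            preprocessing_log=record.log,
            missing_features=sorted(record.missing),
            error={"type": "engine_failure", "message": str(exc)},
        )

    summaries: list[Union[SummaryReport, PeerUnavailable]] = []
    if request.include_peer_summaries and request.peers:
        spec = request.cohort_spec
        if spec is None:
            from .synthetic_fixtures import sepsis_cohort_spec

            spec = sepsis_cohort_spec()
        for peer in request.peers:
            summaries.append(request_summary(peer, spec))

    return CdsResponse(
        status="ok",
        engine_name=descriptor.engine_name,
        engine_version=descriptor.version,
        result=result,
        preprocessing_log=record.log,
        missing_features=sorted(record.missing),
        peer_summaries=summaries,
        ui_payload=compose_ui_payload(result, summaries, record.log),
    )


def response_to_dict(response: CdsResponse) -> dict:
    doc = {
        "status": response.status,
        "engine_name": response.engine_name,
        "engine_version": response.engine_version,
        "result": result_to_dict(response.result) if response.result is not None else None,
        "preprocessing_log": response.preprocessing_log,
        "missing_features": response.missing_features,
        "peer_summaries": [
            s.to_dict() if isinstance(s, SummaryReport) else _to_plain(s) for s in response.peer_summaries
        ],
        "ui_payload": response.ui_payload,
        "error": response.error,
    }
    return doc


# ---------------------------------------------------------------------------
# HTTP surface (stdlib; one wire format shared by CDS clients and peers)


def _make_handler(registry: EngineRegistry, store: Optional[LocalStore], institution_id: str, k: int):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # silent by default
            pass

        def _send(self, code: int, doc: dict):
            body = json.dumps(doc).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self):
            if self.path == "/engines":
                self._send(
                    200,
                    {
                        "engines": [
                            {
                                "engine_name": d.engine_name,
                                "version": d.version,
                                "kind": d.kind,
                                "required_features": [f.name for f in d.required_features],
                                "lookback_hours": d.lookback_hours,
                            }
                            for d in registry.list_engines()
                        ]
                    },
                )
            else:
                self._send(404, {"error": "not found"})

        def do_POST(self):
            length = int(self.headers.get("Content-Length", 0))
            try:
                doc = json.loads(self.rfile.read(length).decode())
            except json.JSONDecodeError as exc:
                self._send(400, {"error": f"malformed JSON: {exc}"})
                return

            if self.path.startswith("/cds/"):
                engine_name = self.path.removeprefix("/cds/")
                try:
                    bundle = parse_bundle(json.dumps(doc["bundle"]))
                    request = CdsRequest(
                        engine_name=engine_name,
                        bundle=bundle,
                        reference_time=parse_instant(doc["reference_time"]),
                    )
                except (KeyError, ValueError) as exc:
                    self._send(400, {"error": str(exc)})
                    return
                self._send(200, response_to_dict(handle_request(request, registry)))
            elif self.path == "/summary":
                if store is None:
                    self._send(503, {"error": "no local store configured"})
                    return
                try:
                    spec = CohortSpec.from_dict(doc["cohort_spec"])
                except (KeyError, ValueError) as exc:
                    self._send(400, {"error": str(exc)})
                    return
                self._send(200, build_summary(store, spec, k=k, institution_id=institution_id).to_dict())
            else:
                self._send(404, {"error": "not found"})

    return Handler


def make_server(
    registry: EngineRegistry,
    store: Optional[LocalStore] = None,
    institution_id: str = "local",
    k: int = DEFAULT_K,
    host: str = "127.0.0.1",
    port: int = 0,
) -> ThreadingHTTPServer:
    """Build (not start) the HTTP server; ``port=0`` picks a free port."""
    return ThreadingHTTPServer((host, port), _make_handler(registry, store, institution_id, k))
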