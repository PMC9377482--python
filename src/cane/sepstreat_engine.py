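"""SepsTreat: the knowledge-based sepsis screening and treatment advisor.

The rule pipeline follows the Sepsis-3 consensus framework:

1. **Screening** — a patient is suspected of sepsis when body temperature is
   strictly above 37.5 °C *and* a blood-culture test or antibiotics have been
   ordered (infection suspicion expressed by the treating physician).
2. **qSOFA** — bedside quick screen over three components: systolic blood
   pressure ≤ 100 mmHg, respiratory rate ≥ 22 /min, altered mentation
   (Glasgow Coma Scale < 15).  Positive at a score of 2 or more.
3. **SOFA** — six organ systems each scored 0–4 from a bundled stratum table
   (half-open intervals).  Sepsis = suspected infection + SOFA ≥ 2 over an
   assumed baseline of 0; septic shock additionally requires vasopressor
   support and lactate > 2 mmol/L.
4. **Treatment recommendation** — an hour-1-bundle-style item list with
   practices already completed marked, so undone treatments stand out.

Missing inputs never raise: each absent organ scores 0 and is listed in
``missing_organs``; absent qSOFA components contribute 0 points.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields
from importlib import resources as importlib_resources
from typing import Optional

from .vocabulary_preprocessing import EngineDescriptor, FeatureRecord, FeatureSpec

QSOFA_SBP_MAX = 100.0  # points when sbp <= this
QSOFA_RESP_RATE_MIN = 22.0  # points when resp_rate >= this
QSOFA_GCS_BELOW = 15.0  # points when gcs < this
SCREEN_TEMPERATURE_C = 37.5  # suspected sepsis when strictly above
SHOCK_LACTATE_MMOL_L = 2.0  # septic shock when strictly above, on vasopressors

SOFA_ORGANS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")

# plausibility bounds for present values: (low, high) inclusive
_PLAUSIBILITY = {
    "gcs": (3, 15),
    "sbp": (30, 300),
    "dbp": (10, 200),
    "resp_rate": (0, 80),
    "body_temperature": (25, 45),
    "pao2": (10, 700),
    "fio2": (0.21, 1.0),
    "platelets": (0, 2000),
    "creatinine": (0.1, 30),
    "total_bilirubin": (0.05, 60),
    "lactate": (0.1, 30),
}


class ContractViolation(RuntimeError):
    """An operation was invoked outside its stated precondition."""


@dataclass(frozen=True)
class SepstreatInput:
    """The 14-item input schema: five vitals, six labs, three order flags.

    Every field is optional; missing values degrade scores toward their floor
    rather than raising.
    """

    gcs: Optional[float] = None  # Glasgow Coma Scale total, 3-15
    sbp: Optional[float] = None  # systolic blood pressure, mmHg
    dbp: Optional[float] = None  # diastolic blood pressure, mmHg
    resp_rate: Optional[float] = None  # breaths per minute
    body_temperature: Optional[float] = None  # degrees Celsius
    pao2: Optional[float] = None  # arterial oxygen partial pressure, mmHg
    fio2: Optional[float] = None  # inspired oxygen fraction, 0.21-1.0
    platelets: Optional[float] = None  # 10^3 / uL
    creatinine: Optional[float] = None  # mg/dL
    total_bilirubin: Optional[float] = None  # mg/dL
    lactate: Optional[float] = None  # mmol/L
    blood_culture_ordered: bool = False
    antibiotics_ordered: bool = False
    vasopressor_ordered: bool = False

    def __post_init__(self):
        for name, (lo, hi) in _PLAUSIBILITY.items():
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or not lo <= value <= hi:
                raise ValueError(f"{name}={value!r} outside plausibility bounds [{lo}, {hi}]")

    @property
    def map_pressure(self) -> Optional[float]:
        """Mean arterial pressure, (SBP + 2 DBP) / 3, when both pressures present."""
        if self.sbp is None or self.dbp is None:
            return None
        return (self.sbp + 2.0 * self.dbp) / 3.0

    @classmethod
    def from_feature_record(cls, record: FeatureRecord) -> "SepstreatInput":
        kwargs = {}
        for f in fields(cls):
            if f.name.endswith("_ordered"):
                kwargs[f.name] = bool(record.value(f.name, False))
            else:
                v = record.value(f.name)
                kwargs[f.name] = float(v) if v is not None else None
        return cls(**kwargs)


@dataclass
class QsofaResult:
    score: int
    components: dict[str, bool]  # low_sbp, high_resp_rate, altered_mentation
    positive: bool
    missing_components: set[str] = field(default_factory=set)


@dataclass
class SofaResult:
    total: int
    organ_subscores: dict[str, int]
    missing_organs: set[str] = field(default_factory=set)


@dataclass
class TreatmentItem:
    item_id: str
    label: str
    completed: bool
    rationale: str


@dataclass
class SepsisAssessment:
    suspected_infection: bool
    qsofa: QsofaResult
    sofa: SofaResult
    sepsis: bool
    septic_shock: bool
    recommendations: list[TreatmentItem] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# bundled scoring table


@dataclass(frozen=True)
class _Stratum:
    lo: float
    hi: float  # half-open [lo, hi)
    subscore: int


class SofaTable:
    """The organ-dysfunction stratum table, loaded from the bundled data file."""

    def __init__(self, strata: dict[str, list[_Stratum]]):
        self._strata = strata
        for organ, rows in strata.items():
            for s in rows:
                if not 0 <= s.subscore <= 4:
                    raise ValueError(f"{organ}: subscore {s.subscore} outside [0, 4]")

    @classmethod
    def bundled(cls) -> "SofaTable":
        pkg = importlib_resources.files("cane.data")
        strata: dict[str, list[_Stratum]] = {}
        with (pkg / "sofa_strata.csv").open() as fh:
            for row in csv.DictReader(fh):
                lo = float(row["stratum_min"]) if row["stratum_min"] else -math.inf
                hi = float(row["stratum_max"]) if row["stratum_max"] else math.inf
                strata.setdefault(row["organ"], []).append(
                    _Stratum(lo=lo, hi=hi, subscore=int(row["subscore"]))
                )
        return cls(strata)

    def subscore(self, organ: str, value: float) -> int:
        for s in self._strata[organ]:
            if s.lo <= value < s.hi:
                return s.subscore
        raise ValueError(f"{organ}: value {value} falls in no stratum")  # pragma: no cover


_TABLE: Optional[SofaTable] = None


def _table() -> SofaTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = SofaTable.bundled()
    return _TABLE


# ---------------------------------------------------------------------------
# rules


def screen_suspected_sepsis(inp: SepstreatInput) -> bool:
    """Fever-plus-workup screening rule.

    True iff body temperature is strictly above 37.5 °C and a blood culture or
    antibiotics have been ordered.  A missing temperature screens out.
    """
    if inp.body_temperature is None:
        return False
    return inp.body_temperature > SCREEN_TEMPERATURE_C and (
        inp.blood_culture_ordered or inp.antibiotics_ordered
    )


def compute_qsofa(inp: SepstreatInput) -> QsofaResult:
    """Quick SOFA over its three components; missing components contribute 0."""
    components = {}
    missing = set()
    if inp.sbp is None:
        components["low_sbp"] = False
        missing.add("low_sbp")
    else:
        components["low_sbp"] = inp.sbp <= QSOFA_SBP_MAX
    if inp.resp_rate is None:
        components["high_resp_rate"] = False
        missing.add("high_resp_rate")
    else:
        components["high_resp_rate"] = inp.resp_rate >= QSOFA_RESP_RATE_MIN
    if inp.gcs is None:
        components["altered_mentation"] = False
        missing.add("altered_mentation")
    else:
        components["altered_mentation"] = inp.gcs < QSOFA_GCS_BELOW
    score = sum(components.values())
    return QsofaResult(score=score, components=components, positive=score >= 2, missing_components=missing)


def compute_sofa(inp: SepstreatInput, table: Optional[SofaTable] = None) -> SofaResult:
    """Six organ subscores from the stratum table; missing organs score 0.

    The cardiovascular subscore uses mean arterial pressure derived from
    SBP/DBP; an existing vasopressor/inotrope order raises it to 3 — the
    boolean order flag cannot distinguish the dose-based strata 2-4, so the
    middle pressor stratum is reported.
    """
    tab = table or _table()
    sub: dict[str, int] = {}
    missing: set[str] = set()

    if inp.pao2 is not None and inp.fio2 is not None:
        if inp.fio2 == 0:
            raise ValueError("fio2 must be positive to form the PaO2/FiO2 ratio")
        sub["respiration"] = tab.subscore("respiration", inp.pao2 / inp.fio2)
    else:
        sub["respiration"] = 0
        missing.add("respiration")

    if inp.platelets is not None:
        sub["coagulation"] = tab.subscore("coagulation", inp.platelets)
    else:
        sub["coagulation"] = 0
        missing.add("coagulation")

    if inp.total_bilirubin is not None:
        sub["liver"] = tab.subscore("liver", inp.total_bilirubin)
    else:
        sub["liver"] = 0
        missing.add("liver")

    if inp.vasopressor_ordered:
        sub["cardiovascular"] = 3
    elif inp.map_pressure is not None:
        sub["cardiovascular"] = tab.subscore("cardiovascular", inp.map_pressure)
    else:
        sub["cardiovascular"] = 0
        missing.add("cardiovascular")

    if inp.gcs is not None:
        sub["cns"] = tab.subscore("cns", inp.gcs)
    else:
        sub["cns"] = 0
        missing.add("cns")

    if inp.creatinine is not None:
        sub["renal"] = tab.subscore("renal", inp.creatinine)
    else:
        sub["renal"] = 0
        missing.add("renal")

    return SofaResult(total=sum(sub.values()), organ_subscores=sub, missing_organs=missing)


def _load_treatment_items() -> list[dict]:
    pkg = importlib_resources.files("cane.data")
    with (pkg / "treatment_items.json").open() as fh:
        return json.load(fh)["items"]


def recommend_treatment(assessment: SepsisAssessment, inp: SepstreatInput) -> list[TreatmentItem]:
    """The bundled treatment item list with already-completed practices marked.

    Completion is inferred from the input schema: an item is marked done when
    its matching order flag is set (or, for lactate, when a lactate value is
    present).  Only valid for a sepsis-positive assessment.
    """
    if not assessment.sepsis:
        raise ContractViolation("recommend_treatment requires assessment.sepsis == True")
    completion = {
        "lactate_present": inp.lactate is not None,
        "blood_culture_ordered": inp.blood_culture_ordered,
        "antibiotics_ordered": inp.antibiotics_ordered,
        "vasopressor_ordered": inp.vasopressor_ordered,
        "never": False,
    }
    items = [
        TreatmentItem(
            item_id=row["item_id"],
            label=row["label"],
            completed=completion[row["completed_when"]],
            rationale=row["rationale"],
        )
        for row in _load_treatment_items()
    ]
    assert len({i.item_id for i in items}) == len(items)
    return items


def assess_sepsis(inp: SepstreatInput) -> SepsisAssessment:
    """Full pipeline: screen, score, classify, recommend.

    Both qSOFA and SOFA are always computed and reported — qSOFA as the rapid
    bedside signal, SOFA as the organ-dysfunction criterion that, combined
    with suspected infection, defines sepsis (baseline SOFA assumed 0).
    """
    suspected = screen_suspected_sepsis(inp)
    qsofa = compute_qsofa(inp)
    sofa = compute_sofa(inp)
    sepsis = suspected and sofa.total >= 2
    septic_shock = bool(
        sepsis and inp.vasopressor_ordered and inp.lactate is not None and inp.lactate > SHOCK_LACTATE_MMOL_L
    )
    assessment = SepsisAssessment(
        suspected_infection=suspected,
        qsofa=qsofa,
        sofa=sofa,
        sepsis=sepsis,
        septic_shock=septic_shock,
    )
    if inp.body_temperature is None:
        assessment.notes.append("body_temperature missing: screening defaults to negative")
    if sofa.missing_organs:
        assessment.notes.append(
            "organs scored 0 for missing data: " + ", ".join(sorted(sofa.missing_organs))
        )
    if sepsis:
        assessment.recommendations = recommend_treatment(assessment, inp)
    return assessment


# qSOFA monitors exactly three clinical components
QSOFA_COMPONENT_COUNT = 3

SEPSTREAT_DESCRIPTOR = EngineDescriptor(
    engine_name="sepstreat",
    version="1",
    kind="knowledge_based",
    required_features=(
        FeatureSpec("gcs", "{score}"),
        FeatureSpec("sbp", "mm[Hg]"),
        FeatureSpec("dbp", "mm[Hg]"),
        FeatureSpec("resp_rate", "/min"),
        FeatureSpec("body_temperature", "Cel"),
        FeatureSpec("pao2", "mm[Hg]", required=False),
        FeatureSpec("fio2", "1", required=False),
        FeatureSpec("platelets", "10*3/uL", required=False),
        FeatureSpec("creatinine", "mg/dL", required=False),
        FeatureSpec("total_bilirubin", "mg/dL", required=False),
        FeatureSpec("lactate", "mmol/L", required=False),
        FeatureSpec("blood_culture_ordered", kind="order"),
        FeatureSpec("antibiotics_ordered", kind="order"),
        FeatureSpec("vasopressor_ordered", kind="order"),
    ),
    lookback_hours=24.0,
)


def run_engine(record: FeatureRecord) -> SepsisAssessment:
    """Plugin entry point: FeatureRecord -> SepsisAssessment."""
    return assess_sepsis(SepstreatInput.from_feature_record(record))
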