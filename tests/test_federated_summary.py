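"""Cohort summaries, small-cell suppression, merging, and the privacy gate."""

import json

import numpy as np
import pandas as pd
import pytest

from cane.federated_summary import (
    CohortSpec,
    HttpPeer,
    LocalPeer,
    LocalStore,
    MergeError,
    PeerUnavailable,
    ReportSchemaError,
    StoreIntegrityError,
    SummaryCell,
    SummaryReport,
    build_summary,
    merge_summaries,
    request_summary,
    suppress_small_cells,
    validate_report_payload,
)
from cane.synthetic_fixtures import CohortProfile, generate_local_store, sepsis_cohort_spec

CONDITION = 999001


def hand_store(n=40, drug_a=12, drug_b=3, deaths=4):
    """A hand-countable store: n cohort members, drug A/B exposure, some deaths."""
    persons = pd.DataFrame({"person_id": [f"p{i}" for i in range(n)],
                            "birth_date": "1960-01-01", "sex_concept": 8507})
    condition = pd.DataFrame({"person_id": [f"p{i}" for i in range(n)],
                              "condition_concept_id": CONDITION,
                              "time": "2024-03-01T12:00:00+00:00"})
    drug_rows = [{"person_id": f"p{i}", "drug_concept_id": 101, "time": "2024-03-01T13:00:00+00:00"}
                 for i in range(drug_a)]
    drug_rows += [{"person_id": f"p{i}", "drug_concept_id": 202, "time": "2024-03-01T13:00:00+00:00"}
                  for i in range(drug_a, drug_a + drug_b)]
    death = pd.DataFrame({"person_id": [f"p{i}" for i in range(deaths)], "time": "2024-03-04T00:00:00+00:00"})
    store = LocalStore.empty()
    store.person, store.condition, store.death = persons, condition, death
    store.drug_exposure = pd.DataFrame(drug_rows)
    return store


def spec():
    return CohortSpec(name="test-cohort", condition_concepts=(CONDITION,))


class TestBuildSummary:
    def test_hand_counted_cells(self):
        report = build_summary(hand_store(), spec(), k=5)
        assert report.n_total == 40
        a = report.cell("drug:101")
        assert (a.count, a.rate, a.suppressed) == (12, pytest.approx(0.30), False)
        b = report.cell("drug:202")
        assert b.suppressed and b.count is None and b.rate is None

    def test_k1_suppresses_nothing(self):
        report = build_summary(hand_store(), spec(), k=1)
        assert all(not c.suppressed for c in report.cells)

    def test_zero_count_reported_not_suppressed(self):
        report = build_summary(hand_store(deaths=0), spec(), k=5)
        death = report.cell("outcome:in_hospital_death")
        assert death.count == 0 and not death.suppressed

    def test_empty_cohort(self):
        empty_spec = CohortSpec(name="none", condition_concepts=(123456,))
        report = build_summary(hand_store(), empty_spec, k=5)
        assert report.n_total == 0 and report.cells == []

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_summary(hand_store(), spec(), k=0)

    def test_generated_store_resolves(self):
        store = generate_local_store(CohortProfile(n=120, sepsis_prevalence=0.4, seed=3))
        report = build_summary(store, sepsis_cohort_spec(), k=10)
        assert report.n_total > 0
        for cell in report.cells:
            assert cell.suppressed or cell.count == 0 or cell.count >= 10


class TestSuppression:
    def test_direct_rule(self):
        report = SummaryReport(
            institution_id="a", cohort_name="c", n_total=40, k_threshold=5,
            cells=[SummaryCell("x", 12, 0.3), SummaryCell("y", 3, 0.075)],
        )
        out = suppress_small_cells(report, 5)
        assert not out.cell("x").suppressed
        assert out.cell("y").suppressed

    def test_idempotent(self):
        report = suppress_small_cells(
            SummaryReport(institution_id="a", cohort_name="c", n_total=40, k_threshold=5,
                          cells=[SummaryCell("y", 3, 0.075)]),
            5,
        )
        again = suppress_small_cells(report, 5)
        assert again.cells == report.cells

    def test_k1_identity(self):
        report = SummaryReport(institution_id="a", cohort_name="c", n_total=40, k_threshold=1,
                               cells=[SummaryCell("x", 1, 0.025)])
        assert suppress_small_cells(report, 1).cells == report.cells


def random_report(rng, institution, k=5):
    labels = [f"drug:{i}" for i in range(rng.integers(1, 6))] + ["outcome:in_hospital_death"]
    n = int(rng.integers(20, 200))
    cells = []
    for label in labels:
        count = int(rng.integers(0, 30))
        cells.append(SummaryCell(label, count, count / n))
    return suppress_small_cells(
        SummaryReport(institution_id=institution, cohort_name="c", n_total=n, cells=cells, k_threshold=k), k
    )


class TestMerge:
    def test_counts_add(self):
        r1 = build_summary(hand_store(drug_a=12), spec(), k=5, institution_id="site1")
        r2 = build_summary(hand_store(drug_a=20), spec(), k=5, institution_id="site2")
        merged = merge_summaries([r1, r2])
        assert merged.cell("drug:101").count == 32
        assert merged.n_total == 80

    def test_single_report_identity_modulo_provenance(self):
        r = build_summary(hand_store(), spec(), k=5, institution_id="solo")
        merged = merge_summaries([r])
        assert merged.n_total == r.n_total
        assert merged.cohort_name == r.cohort_name
        for cell in r.cells:
            m = merged.cell(cell.label)
            if cell.suppressed:
                # a site-suppressed cell stays opaque after merging one site
                assert m.partially_suppressed
            else:
                assert (m.count, m.rate) == (cell.count, cell.rate)

    def test_mismatched_cohorts_rejected(self):
        r1 = build_summary(hand_store(), spec(), k=5)
        r2 = build_summary(hand_store(), CohortSpec(name="different", condition_concepts=(CONDITION,)), k=5)
        with pytest.raises(MergeError):
            merge_summaries([r1, r2])

    def test_suppression_survives_merge_on_random_pairs(self):
        """After merging 200 random report pairs, no cell has 0 < count < k."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            merged = merge_summaries([random_report(rng, "a"), random_report(rng, "b")])
            for cell in merged.cells:
                assert cell.suppressed or cell.count == 0 or cell.count >= merged.k_threshold

    def test_commutative_and_associative_on_unsuppressed_cells(self):
        rng = np.random.default_rng(88)
        a, b, c = (random_report(rng, s) for s in "abc")
        ab_c = merge_summaries([merge_summaries([a, b]), c])
        a_bc = merge_summaries([a, merge_summaries([b, c])])
        ba = merge_summaries([b, a])
        ab = merge_summaries([a, b])
        for left, right in ((ab, ba), (ab_c, a_bc)):
            for cell in left.cells:
                other = right.cell(cell.label)
                if not cell.suppressed and not other.suppressed and not cell.partially_suppressed:
                    assert cell.count == other.count


class TestPrivacy:
    def test_wire_format_carries_no_person_level_fields(self):
        report = build_summary(hand_store(), spec(), k=5)
        text = report.to_json()
        for forbidden in ("person_id", "birth_date", "visit_id"):
            assert forbidden not in text
        # only timestamp is the report's own generation time
        doc = json.loads(text)
        time_keys = [k for k in doc if "time" in k]
        assert time_keys == ["generated_time"]

    def test_validator_rejects_person_level_payload(self):
        doc = build_summary(hand_store(), spec(), k=5).to_dict()
        doc["cells"].append({"label": "leak", "count": 1, "rate": 0.01, "person_id": "p3"})
        with pytest.raises(ReportSchemaError, match="person_id"):
            validate_report_payload(doc)


class TestStoreIntegrity:
    def test_dangling_foreign_key_rejected(self):
        store = hand_store()
        store.death = pd.DataFrame({"person_id": ["ghost"], "time": ["2024-03-04T00:00:00+00:00"]})
        with pytest.raises(StoreIntegrityError, match="death"):
            store.validate()

    def test_nonpositive_concept_rejected(self):
        store = hand_store()
        store.condition.loc[0, "condition_concept_id"] = -1
        with pytest.raises(StoreIntegrityError):
            store.validate()

    def test_csv_round_trip(self, tmp_path):
        store = hand_store()
        store.save(tmp_path / "store")
        loaded = LocalStore.load(tmp_path / "store")
        report = build_summary(loaded, spec(), k=5)
        assert report.cell("drug:101").count == 12


class TestPeerTransport:
    def test_loopback_equals_local_build(self):
        store = hand_store()
        peer = LocalPeer(store, "siteX", k=5)
        remote = request_summary(peer, spec())
        local = build_summary(store, spec(), k=5, institution_id="siteX")
        assert isinstance(remote, SummaryReport)
        assert remote.n_total == local.n_total
        assert [(c.label, c.count, c.suppressed) for c in remote.cells] == [
            (c.label, c.count, c.suppressed) for c in local.cells
        ]

    def test_injected_person_fields_blocked(self):
        class LeakyPeer:
            endpoint = "local://leaky"

            def request(self, cohort_spec):
                doc = build_summary(hand_store(), spec(), k=5).to_dict()
                doc["person_id"] = "p1"
                return doc

        result = request_summary(LeakyPeer(), spec())
        assert isinstance(result, PeerUnavailable)
        assert "privacy" in result.reason

    def test_unreachable_peer_degrades(self):
        peer = HttpPeer("http://127.0.0.1:1/summary", timeout=0.2)
        result = request_summary(peer, spec())
        assert isinstance(result, PeerUnavailable)
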