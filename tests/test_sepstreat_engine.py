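"""Screening rule, qSOFA, SOFA table, Sepsis-3 composition, and treatment list."""

import itertools

import numpy as np
import pytest

from cane.sepstreat_engine import (
    ContractViolation,
    SepstreatInput,
    assess_sepsis,
    compute_qsofa,
    compute_sofa,
    recommend_treatment,
    screen_suspected_sepsis,
)
from cane.synthetic_fixtures import CohortProfile, sample_patient


def make_input(**kwargs):
    defaults = dict(
        gcs=15, sbp=120, dbp=80, resp_rate=16, body_temperature=37.0,
        pao2=95, fio2=0.21, platelets=250, creatinine=0.8, total_bilirubin=0.5, lactate=1.0,
    )
    defaults.update(kwargs)
    return SepstreatInput(**defaults)


def sample_to_input(sample):
    v = sample.values
    return SepstreatInput(
        gcs=v.get("gcs"), sbp=v.get("sbp"), dbp=v.get("dbp"), resp_rate=v.get("resp_rate"),
        body_temperature=v.get("body_temperature"), pao2=v.get("pao2"), fio2=v.get("fio2"),
        platelets=v.get("platelets"), creatinine=v.get("creatinine"),
        total_bilirubin=v.get("total_bilirubin"), lactate=v.get("lactate"),
        blood_culture_ordered=sample.blood_culture_ordered,
        antibiotics_ordered=sample.antibiotics_ordered,
        vasopressor_ordered=sample.vasopressor_ordered,
    )


class TestScreening:
    @pytest.mark.parametrize(
        "temp,culture,antibiotics,expected",
        [
            (38.0, True, False, True),
            (37.5, True, False, False),  # strictly above the threshold
            (39.0, False, False, False),  # fever alone is not enough
            (37.6, False, True, True),
            (None, True, True, False),  # missing temperature screens out
        ],
    )
    def test_rule(self, temp, culture, antibiotics, expected):
        inp = make_input(body_temperature=temp, blood_culture_ordered=culture, antibiotics_ordered=antibiotics)
        assert screen_suspected_sepsis(inp) is expected

    def test_equivalent_to_truth_table(self):
        """Grid of temperature x order flags matches brute-force evaluation."""
        for temp in np.arange(36.0, 40.01, 0.1):
            temp = round(float(temp), 1)
            for culture, abx in itertools.product([False, True], repeat=2):
                inp = make_input(body_temperature=temp, blood_culture_ordered=culture, antibiotics_ordered=abx)
                assert screen_suspected_sepsis(inp) == ((temp > 37.5) and (culture or abx))


class TestQsofa:
    def test_all_normal(self):
        r = compute_qsofa(make_input(sbp=120, resp_rate=16, gcs=15))
        assert r.score == 0 and not r.positive

    def test_all_deranged(self):
        r = compute_qsofa(make_input(sbp=90, resp_rate=24, gcs=13))
        assert r.score == 3 and r.positive
        assert r.components == {"low_sbp": True, "high_resp_rate": True, "altered_mentation": True}

    def test_exhaustive_popcount(self):
        """All 2^3 component states: score equals the number of true components."""
        for low_sbp, high_rr, altered in itertools.product([False, True], repeat=3):
            inp = make_input(
                sbp=95 if low_sbp else 130,
                resp_rate=25 if high_rr else 14,
                gcs=12 if altered else 15,
            )
            r = compute_qsofa(inp)
            assert r.score == int(low_sbp) + int(high_rr) + int(altered)
            assert r.positive == (r.score >= 2)

    def test_boundary_cutoffs(self):
        assert compute_qsofa(make_input(sbp=100)).components["low_sbp"]  # <= 100
        assert not compute_qsofa(make_input(sbp=101)).components["low_sbp"]
        assert compute_qsofa(make_input(resp_rate=22)).components["high_resp_rate"]  # >= 22
        assert not compute_qsofa(make_input(gcs=15)).components["altered_mentation"]  # < 15

    def test_missing_components_score_zero(self):
        r = compute_qsofa(SepstreatInput())
        assert r.score == 0
        assert r.missing_components == {"low_sbp", "high_resp_rate", "altered_mentation"}


class TestSofa:
    def test_fully_normal_is_zero(self):
        r = compute_sofa(make_input(pao2=94.5, fio2=0.21, platelets=250, total_bilirubin=0.5,
                                    sbp=120, dbp=75, gcs=15, creatinine=0.8))
        assert r.total == 0
        assert all(v == 0 for v in r.organ_subscores.values())
        assert r.missing_organs == set()

    def test_worst_strata_ceiling(self):
        inp = make_input(
            pao2=30, fio2=0.6,  # ratio 50 -> 4
            platelets=10, total_bilirubin=15.0, creatinine=6.0, gcs=4,
            sbp=60, dbp=30, vasopressor_ordered=True,
        )
        r = compute_sofa(inp)
        # vasopressor order caps cardiovascular at subscore 3 (dose unknown)
        assert r.organ_subscores == {
            "respiration": 4, "coagulation": 4, "liver": 4, "cardiovascular": 3, "cns": 4, "renal": 4,
        }
        assert r.total == 23

    def test_missing_organs_score_zero_and_are_listed(self):
        r = compute_sofa(SepstreatInput(gcs=14))
        assert r.total == 1  # only cns scored
        assert r.missing_organs == {"respiration", "coagulation", "liver", "cardiovascular", "renal"}

    def test_total_is_sum_of_subscores_on_random_inputs(self):
        profile = CohortProfile(n=500, sepsis_prevalence=0.5, seed=21)
        for i in range(500):
            r = compute_sofa(sample_to_input(sample_patient(profile, i)))
            assert r.total == sum(r.organ_subscores.values())
            assert all(0 <= v <= 4 for v in r.organ_subscores.values())

    def test_agrees_with_independent_oracle(self):
        """Table-driven engine vs the generator's straight-line oracle, 1000 draws."""
        profile = CohortProfile(n=1000, sepsis_prevalence=0.5, seed=22)
        for i in range(1000):
            sample = sample_patient(profile, i)
            assert compute_sofa(sample_to_input(sample)).total == sample.truth.expected_sofa

    def test_implausible_input_rejected(self):
        with pytest.raises(ValueError, match="fio2"):
            make_input(fio2=0.0)  # below physical minimum; also guards the ratio
        with pytest.raises(ValueError, match="body_temperature"):
            make_input(body_temperature=50)

    @pytest.mark.parametrize(
        "field,worse",
        [
            ("platelets", 40), ("total_bilirubin", 7.0), ("creatinine", 4.0),
            ("gcs", 8), ("sbp", 70), ("pao2", 50),
        ],
    )
    def test_monotone_in_single_input(self, field, worse):
        base = make_input()
        worse_input = make_input(**{field: worse})
        assert compute_sofa(worse_input).total >= compute_sofa(base).total
        assert compute_qsofa(worse_input).score >= compute_qsofa(base).score


class TestAssessment:
    def test_screened_in_with_organ_dysfunction_is_sepsis(self):
        inp = make_input(body_temperature=38.5, blood_culture_ordered=True,
                         platelets=90, creatinine=2.5, total_bilirubin=2.5)
        a = assess_sepsis(inp)
        assert a.suspected_infection and a.sofa.total >= 2
        assert a.sepsis
        assert a.recommendations

    def test_screened_out_despite_high_sofa(self):
        inp = make_input(body_temperature=36.8, platelets=15, creatinine=6.0,
                         total_bilirubin=13.0, gcs=5)
        a = assess_sepsis(inp)
        assert a.sofa.total >= 8
        assert not a.sepsis and not a.recommendations

    def test_septic_shock_conjunction(self):
        inp = make_input(body_temperature=38.5, blood_culture_ordered=True, vasopressor_ordered=True,
                         lactate=3.1, platelets=90, creatinine=2.5)
        a = assess_sepsis(inp)
        assert a.sepsis and a.septic_shock

    def test_no_shock_without_lactate_elevation(self):
        inp = make_input(body_temperature=38.5, blood_culture_ordered=True, vasopressor_ordered=True,
                         lactate=1.5, platelets=90, creatinine=2.5)
        a = assess_sepsis(inp)
        assert a.sepsis and not a.septic_shock

    def test_invariants_hold_on_random_inputs(self):
        profile = CohortProfile(n=300, sepsis_prevalence=0.5, seed=23)
        for i in range(300):
            a = assess_sepsis(sample_to_input(sample_patient(profile, i)))
            assert 0 <= a.qsofa.score <= 3
            assert 0 <= a.sofa.total <= 24
            if a.sepsis:
                assert a.suspected_infection
            if a.septic_shock:
                assert a.sepsis


class TestRecommendations:
    def septic_input(self, **kwargs):
        return make_input(body_temperature=38.5, blood_culture_ordered=True,
                          platelets=90, creatinine=2.5, **kwargs)

    def test_completed_marks_follow_orders(self):
        inp = self.septic_input(antibiotics_ordered=True)
        a = assess_sepsis(inp)
        by_id = {i.item_id: i for i in a.recommendations}
        assert by_id["broad_spectrum_antibiotics"].completed
        assert by_id["blood_cultures"].completed  # culture ordered in septic_input
        assert by_id["measure_lactate"].completed  # lactate value present
        assert not by_id["vasopressors"].completed
        assert not by_id["crystalloid_fluids"].completed

    def test_nothing_done_nothing_marked(self):
        inp = make_input(body_temperature=38.5, antibiotics_ordered=True, lactate=None,
                         platelets=90, creatinine=2.5, blood_culture_ordered=False)
        # antibiotics order both screens the patient in and marks its item; clear it
        a = assess_sepsis(inp)
        marks = {i.item_id: i.completed for i in a.recommendations}
        assert marks == {
            "measure_lactate": False,
            "blood_cultures": False,
            "broad_spectrum_antibiotics": True,
            "crystalloid_fluids": False,
            "vasopressors": False,
        }

    def test_contract_requires_sepsis(self):
        a = assess_sepsis(make_input())
        assert not a.sepsis
        with pytest.raises(ContractViolation):
            recommend_treatment(a, make_input())

    def test_item_ids_unique_over_random_inputs(self):
        profile = CohortProfile(n=500, sepsis_prevalence=0.9, seed=24)
        seen_sepsis = 0
        for i in range(500):
            a = assess_sepsis(sample_to_input(sample_patient(profile, i)))
            if a.sepsis:
                seen_sepsis += 1
                ids = [t.item_id for t in a.recommendations]
                assert len(ids) == len(set(ids))
        assert seen_sepsis > 100  # the property was actually exercised
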