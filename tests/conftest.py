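import json

import pytest

from cane.synthetic_fixtures import CohortProfile


@pytest.fixture(scope="session")
def small_profile():
    return CohortProfile(n=50, sepsis_prevalence=0.4, seed=7)


@pytest.fixture(scope="session")
def cohort_200():
    from cane.synthetic_fixtures import generate_cohort

    profile = CohortProfile(n=200, sepsis_prevalence=0.3, seed=7)
    bundles, truth = generate_cohort(profile)
    return profile, bundles, truth


@pytest.fixture()
def febrile_bundle_json():
    """A hand-built two-entry bundle: one Patient, one temperature Observation."""
    return json.dumps(
        {
            "resourceType": "Bundle",
            "id": "b-1",
            "type": "collection",
            "entry": [
                {
                    "resource": {
                        "resourceType": "Patient",
                        "id": "pat-1",
                        "birthDate": "1958-04-02",
                        "gender": "female",
                    }
                },
                {
                    "resource": {
                        "resourceType": "Observation",
                        "id": "obs-1",
                        "status": "final",
                        "subject": {"reference": "Patient/pat-1"},
                        "code": {
                            "coding": [
                                {
                                    "system": "http://loinc.org",
                                    "code": "8310-5",
                                    "display": "Body temperature",
                                }
                            ]
                        },
                        "valueQuantity": {"value": 38.2, "unit": "Cel"},
                        "effectiveDateTime": "2024-03-01T10:30:00+00:00",
                    }
                },
            ],
        }
    )
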