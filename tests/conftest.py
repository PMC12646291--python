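import pytest

import piloscore as ps


@pytest.fixture(scope="session")
def weights():
    return ps.default_weight_table()


@pytest.fixture(scope="session")
def fixture_cohort():
    return ps.reconstruct_fixture()


@pytest.fixture(scope="session")
def fixture_scores(fixture_cohort, weights):
    records = fixture_cohort.records
    scores = [ps.compute_score(r, weights).total for r in records]
    labels = [bool(r.recurrence) for r in records]
    return scores, labels


def make_record(**overrides):
    """A valid mid-range record; override any field."""
    base = dict(
        patient_id="T001",
        sex="female",
        age=30,
        bmi=24.0,
        hairy_back=False,
        diabetes=False,
        prior_recurrence=False,
        n_midline_pits=3,
        lateral_pits=False,
        distance_to_anus_cm=7.0,
        prior_abscess=False,
    )
    base.update(overrides)
    return ps.PatientRecord(**base)


#: the all-minimal and all-maximal records under the default weights
MIN_RECORD_KW = dict(sex="female", bmi=24.0, hairy_back=False, diabetes=False,
                     prior_recurrence=False, n_midline_pits=3, lateral_pits=False,
                     distance_to_anus_cm=7.0, prior_abscess=False)
MAX_RECORD_KW = dict(sex="male", bmi=34.0, hairy_back=True, diabetes=True,
                     prior_recurrence=True, n_midline_pits=12, lateral_pits=True,
                     distance_to_anus_cm=3.0, prior_abscess=True)
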