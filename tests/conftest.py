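import datetime

import pytest

from cohortlink import AnalysisConfig, PatientRecord, run_pipeline
from cohortlink.synthetic_cohort import CohortGenConfig, generate


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


def make_patient():
    """A hand-built adolescent transferring out of tertiary care on 2010-06-01."""
    return PatientRecord(
        patient_id="P1", sex="female",
        enrolment_date=datetime.date(2004, 2, 1),
        art_start_date=datetime.date(2004, 5, 1),
        transfer_out_date=datetime.date(2010, 6, 1),
        age_at_enrolment=6.0, age_at_art_start=6.3, age_at_transfer=12.3,
        origin_facility="ORIG", origin_level="tertiary",
        cd4_at_transfer=640.0, vl_at_transfer=50.0,
    )


@pytest.fixture
def patient():
    return make_patient()


@pytest.fixture(scope="session")
def synth():
    """A mid-sized synthetic cohort shared across tests (fixed seed)."""
    return generate(CohortGenConfig(n_patients=1200, seed=11))


@pytest.fixture(scope="session")
def synth_results(synth):
    outcomes, assessments = run_pipeline(
        synth.patients, synth.events, synth.duplicates, AnalysisConfig())
    return outcomes, assessments
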