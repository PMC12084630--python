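import numpy as np
import pytest
from hypothesis import settings

from helmet.data_model import (
    PatientRecord,
    ScanRecord,
    StaticProfile,
    TimedValue,
)
from helmet.observation_builder import FeatureSchema, build_observation_table
from helmet.synthetic_cohort import SimConfig, simulate_cohort
from helmet.target_builder import add_targets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_two_scan_patient(t0: int = 10, gap: int = 40, mls=(2.0, 9.0)) -> PatientRecord:
    """Toy patient with scans at t0 and t0+gap; follow-up well past both."""
    return PatientRecord(
        static=StaticProfile(patient_id="toy", admission_hour=float(t0), features={}),
        series=[TimedValue("glucose", float(t0), 140.0)],
        scans=[
            ScanRecord(hour=float(t0), mls_mm=mls[0]),
            ScanRecord(hour=float(t0 + gap), mls_mm=mls[1]),
        ],
        end_hour=float(t0 + gap + 30),
    )


@pytest.fixture
def two_scan_patient() -> PatientRecord:
    return make_two_scan_patient()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimConfig(n_patients=20, seed=1))


@pytest.fixture(scope="session")
def schema() -> FeatureSchema:
    return FeatureSchema()


@pytest.fixture(scope="session")
def small_obs(small_cohort, schema):
    obs = build_observation_table(small_cohort, schema)
    return add_targets(obs, small_cohort, 24)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
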