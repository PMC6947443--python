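import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cervixsign.evaluation import CaseRecord
from cervixsign.measurement import measure_case
from cervixsign.simulate import CohortParams, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale synthetic cohort (n=96, default parameters)."""
    return generate_cohort(CohortParams(seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for parameter-recovery and calibration checks."""
    return generate_cohort(CohortParams(n_cases=5000, seed=0))


def cohort_records(cases) -> list[CaseRecord]:
    """Run the measurement protocol and join to ground truth."""
    return [
        CaseRecord(
            case_id=c.case_id,
            angle_deg=(m := measure_case(c.landmarks)).combined_deg,
            adhesion=c.adhesion,
            ga_weeks=c.ga_weeks,
            version=m.version,
        )
        for c in cases
    ]


@pytest.fixture(scope="session")
def large_records(large_cohort):
    return cohort_records(large_cohort)
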