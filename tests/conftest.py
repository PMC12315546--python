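import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icvnorm.cohort import DEFAULT_GROUP_SIZES, CohortSpec
from icvnorm.cohort import generate_cohort
from icvnorm.qc import aggregate_subjects

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A compact six-group cohort spec (60 subjects per cell)."""
    return CohortSpec(
        group_sizes={g: 60 for g in DEFAULT_GROUP_SIZES}, seed=123
    )


@pytest.fixture(scope="session")
def small_scans(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_subjects(small_scans):
    subjects, _ = aggregate_subjects(small_scans)
    return subjects


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
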