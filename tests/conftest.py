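import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hippoquant.cohort import CohortSpec, sample_cohort
from hippoquant.pipeline import run_pipeline
from hippoquant.tissue import AcquisitionParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded synthetic cohort (14 controls, 27 patients)."""
    return sample_cohort(CohortSpec())


@pytest.fixture(scope="session")
def default_report(default_cohort):
    """Full default pipeline run (simulate -> measure -> classify)."""
    # run_pipeline resamples the same cohort deterministically
    return run_pipeline()


@pytest.fixture()
def tiny_spec() -> CohortSpec:
    """A small cohort for fast end-to-end checks."""
    return CohortSpec(n_controls=3, n_patients=4, seed=7)
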