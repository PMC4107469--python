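import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnvpheno as cp

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, shared across tests (seed 1)."""
    return cp.generate_study(seed=1)


@pytest.fixture(scope="session")
def classified(study):
    return cp.classify_cohort(study.calls, study.db)


@pytest.fixture(scope="session")
def truth_clusters(study):
    return np.array(
        [study.truth.subject_clusters[s] for s in study.matrix.subjects]
    )
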