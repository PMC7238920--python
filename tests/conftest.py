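import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_cohort():
    """One synthetic cohort at the study dimensions (31/34/22)."""
    from tractnorm import SimulationConfig, generate_cohort

    cohort, truth = generate_cohort(SimulationConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def scored_study(study_cohort):
    """The study-dimension cohort scored end to end (shared, read-only)."""
    from tractnorm import TractSeverityModel

    cohort, _ = study_cohort
    model = TractSeverityModel(cohort)
    return model.fit(subset_size=25, n_perm=200, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
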