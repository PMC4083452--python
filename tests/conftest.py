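import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aslrisk.synthetic import CohortConfig, ParticipantRecord

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_config():
    """Tiny noise-free, drift-free study for exact round-trip checks."""
    return CohortConfig(n_participants=4, seed=11, asl_noise_sd=0.0,
                        drift_slope=0.0, n_trails_missing=0)


@pytest.fixture(scope="session")
def study_cohort():
    """One default-condition cohort at the emulated study's size."""
    from aslrisk.synthetic import generate_cohort
    config = CohortConfig(n_participants=71, seed=3)
    records, truth = generate_cohort(config)
    return config, records, truth


def make_record(**overrides) -> ParticipantRecord:
    base = dict(id="sub-001", age=72.0, sex="female", apoe4=False,
                sbp=120.0, dbp=70.0, antihypertensive=False, diabetes=False,
                cvd=False, afib=False, tia_stroke=False, smoker=False,
                drs_total=140.0, cvlt_trials_1_5=45.0, trails_b_seconds=75.0,
                wml_volume_mm3=None)
    base.update(overrides)
    return ParticipantRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(42)
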