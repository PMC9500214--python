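import numpy as np
import pytest

from gaitclamp.synthetic_gait import CalibrationParams, CohortConfig, make_cohort


@pytest.fixture(scope="session")
def calib() -> CalibrationParams:
    return CalibrationParams()


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Small, fast cohort for unit tests (3 participants, 3-min trials)."""
    return CohortConfig(n_participants=3, trial_duration=180.0, seed=7)


@pytest.fixture(scope="session")
def profile(small_config):
    return make_cohort(small_config)[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
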