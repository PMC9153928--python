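import numpy as np
import pytest

from dualnback import PipelineConfig, score_cohort, simulate_cohort
from dualnback.cohort import Population


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject, 45-trial cohort shared across tests (seeded)."""
    design = PipelineConfig(n_subjects=6, n_trials=45).design()
    log, profiles = simulate_cohort(design, Population(), seed=42)
    return log, profiles


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    log, _ = small_cohort
    return score_cohort(log)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
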