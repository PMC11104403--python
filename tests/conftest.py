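import numpy as np
import pytest

from bartmodel import (
    CohortConfig,
    InferenceConfig,
    ParticipantParams,
    TaskConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def task_main():
    return TaskConfig.preset("main", shuffle_seed=0)


@pytest.fixture(scope="session")
def agent():
    """A mid-range agent used across unit tests."""
    return ParticipantParams(
        prior_belief=0.85, learning_rate=0.2, risk_taking=0.6, inverse_temperature=2.0
    )


@pytest.fixture(scope="session")
def tiny_study():
    """Small two-block study for IO/analysis tests (10 participants)."""
    cohort = CohortConfig(n_participants=10, seed=42)
    return simulate_study(cohort)


@pytest.fixture(scope="session")
def fast_inference():
    """Reduced-draw fast-backend settings for unit-test fits."""
    return InferenceConfig(n_chains=4, n_iterations=1500, n_warmup=1000, seed=0)
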