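import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteosim import (
    MODEL_1,
    MODEL_2,
    GridConfig,
    generate_synthetic_leg,
    run_grid,
    summarize_table,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def model1_leg():
    return generate_synthetic_leg(MODEL_1)


@pytest.fixture(scope="session")
def model2_leg():
    return generate_synthetic_leg(MODEL_2)


@pytest.fixture(scope="session")
def default_records():
    """The full default study grid (420 simulations)."""
    return run_grid(GridConfig())


@pytest.fixture(scope="session")
def default_table(default_records):
    return summarize_table(default_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
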