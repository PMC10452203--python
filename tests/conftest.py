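import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vocaltab.model import ModelConfig
from vocaltab.synthetic import generate_cohort, small_cohort_spec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strong_cohort():
    """Reduced cohort with a strong class signal (effect 2 sd, 20 informative)."""
    return generate_cohort(small_cohort_spec())


@pytest.fixture(scope="session")
def null_cohort():
    """Same cohort shape with zero class effect."""
    return generate_cohort(small_cohort_spec(effect_size=0.0))


@pytest.fixture(scope="session")
def tiny_model_config():
    """A transformer small enough to train in seconds."""
    return ModelConfig(
        n_features=20, embed_dim=16, n_encoders=2, n_heads=1, rho=2, head_hidden=64
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
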