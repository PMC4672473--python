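import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vatariff import GeneratorSpec, TrainConfig, generate, train_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Well-separated 4-cause generator spec small enough for fast training."""
    return GeneratorSpec(
        n_causes=4,
        signature_items=4,
        background_items=6,
        hce_items=2,
        p_sig=0.9,
        p_bg=0.05,
        p_drop=0.05,
        n_per_cause=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def sep_dataset(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def fast_config():
    return TrainConfig(bootstrap_b=60)


@pytest.fixture(scope="session")
def trained_small(sep_dataset, fast_config):
    return train_model(sep_dataset, fast_config, seed=5)
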