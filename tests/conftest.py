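import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import underice as ui

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_zero_noise():
    """Three-metal, zero-noise study-shaped dataset plus its configuration."""
    cfg = ui.default_config(seed=7, noise_cv=0.0, metals=("As", "Cu", "Zn"))
    return cfg, ui.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_zero_noise_result(small_zero_noise):
    """Pipeline result on the small zero-noise dataset."""
    _, dataset = small_zero_noise
    return ui.run_pipeline(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
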