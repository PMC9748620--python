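import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import xrfpit as xp

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> xp.GeneratorConfig:
    return xp.default_config()


@pytest.fixture(scope="session")
def noiseless_cfg() -> xp.GeneratorConfig:
    """Deterministic generator: no Poisson noise, no fruit-level dispersion."""
    return xp.default_config(
        poisson_noise=False, within_fruit_cv=0.0, between_fruit_cv=0.0
    )


@pytest.fixture(scope="session")
def small_balanced(default_cfg) -> xp.LabelledSpectraSet:
    """20 fruit per class x 6 points, default noise; shared across tests."""
    return xp.generate_balanced_study(default_cfg, 20, seed=42)


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
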