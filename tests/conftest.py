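import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def skill_map():
    """Session-wide error-to-noise map (moderate grid for speed)."""
    from hapticdyad.protocol import build_skill_map

    return build_skill_map(trials_per_point=3, base_seed=777)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
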