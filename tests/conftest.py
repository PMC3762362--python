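import numpy as np
import pytest

from cosmoskin import KineticParams, ObservationConfig


@pytest.fixture(scope="session")
def wt_params() -> KineticParams:
    """Wild-type study conditions (reference measurement set)."""
    return KineticParams.from_construct("wt")


@pytest.fixture
def obs_clean() -> ObservationConfig:
    """Observation settings with no degradation: the identity limit."""
    return ObservationConfig(
        t_min=0.0, bleach_rate_per_power=0.0, loc_sigma=0.0,
        nonspecific_rate=0.0, frame_interval=1e-6, seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
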