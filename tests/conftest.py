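import numpy as np
import pytest

from hensight.flock import FlockSimConfig
from hensight.pipeline import SeasonConfig, run_synthetic_season


@pytest.fixture(scope="session")
def small_season():
    """A compact synthetic campaign shared by the statistics tests.

    8 days x 2 periods x 3 treatments of 30-s recordings: large enough
    for every cell of the comparison tables to hold several recording
    means, small enough to simulate in seconds.
    """
    cfg = SeasonConfig(n_days=8, recording_s=30, seed=11)
    return run_synthetic_season(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_flock(**kwargs) -> FlockSimConfig:
    defaults = dict(n_birds=5, duration_s=10, seed=1)
    defaults.update(kwargs)
    return FlockSimConfig(**defaults)
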