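import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import periotherm as pt

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config():
    """Reduced-size phantom (64 x 160, 12 s) for fast imaging-chain tests."""
    return pt.PhantomConfig(frame_rows=64, frame_cols=160, trial_duration=12, seed=7)


@pytest.fixture
def far_config():
    """Small phantom with canthi far apart so the hot-spot tails do not
    overlap at double precision (exactness tests)."""
    return pt.PhantomConfig(
        frame_rows=64,
        frame_cols=160,
        canthus_centers=((28, 40), (28, 120)),
        trial_duration=12,
        seed=7,
    )
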