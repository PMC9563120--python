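import pytest

from myoforge import TraceModel, build_schedule, simulate_trace
from myoforge.protocol import DEFAULT_TRAIN_PERIOD_S


@pytest.fixture(scope="session")
def quadrant_schedule():
    """Default-period schedule spanning one 5-min analysis quadrant."""
    return build_schedule(DEFAULT_TRAIN_PERIOD_S, 300.0)


@pytest.fixture(scope="session")
def quadrant_trace(quadrant_schedule):
    """Alternating-pattern noisy quadrant trace with a fixed seed."""
    return simulate_trace(quadrant_schedule, TraceModel(seed=1))


@pytest.fixture(scope="session")
def noiseless_quadrant_trace(quadrant_schedule):
    return simulate_trace(quadrant_schedule, TraceModel(seed=1, noise_sd=0.0))
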