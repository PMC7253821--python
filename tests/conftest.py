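import numpy as np
import pytest

from spikevar import KernelSpec, make_fixture


@pytest.fixture(scope="session")
def kernel():
    return KernelSpec()


@pytest.fixture(scope="session")
def pure_100():
    """100 trials, constant 20 spikes/s, no rate noise."""
    _, ts = make_fixture("pure_constant", seed=11)
    return ts


@pytest.fixture(scope="session")
def noisy_100():
    """100 trials, constant 20 spikes/s, additive rate noise sigma=10."""
    _, ts = make_fixture("noisy_constant", seed=11)
    return ts


@pytest.fixture(scope="session")
def task_noisy_100():
    """100 trials, 5->45 spikes/s task-epoch ramp, rate noise sigma=5."""
    _, ts = make_fixture("task_epoch_noisy", seed=11)
    return ts
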