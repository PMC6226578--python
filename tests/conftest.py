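import numpy as np
import pytest

from hln.signals import SpikeTrain, SpikeTrainSet, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return TimeGrid(dt=1.0, n_bins=2000)


def random_spike_set(
    rng: np.random.Generator,
    n_exc: int,
    n_inh: int,
    duration_ms: float,
    rate_hz: float = 10.0,
) -> SpikeTrainSet:
    """Homogeneous-Poisson spike set used as a generic fitting input."""
    out = SpikeTrainSet()
    sid = 0
    for label, n in (("excitatory", n_exc), ("inhibitory", n_inh)):
        for _ in range(n):
            k = rng.poisson(rate_hz * duration_ms / 1000.0)
            times = np.sort(rng.uniform(0, duration_ms - 1e-6, k))
            out.add(sid, SpikeTrain(times, label, ensemble_id=sid % 3))
            sid += 1
    return out


@pytest.fixture
def spike_set(rng, grid):
    return random_spike_set(rng, n_exc=6, n_inh=2, duration_ms=grid.duration)
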