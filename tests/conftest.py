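import numpy as np
import pytest

from eegdyn import Segment, WaveletConfig, gen_switching_segment
from eegdyn.synth import partition_topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_topologies():
    """Two clearly distinct module partitions over 8 channels."""
    return [
        partition_topology([0, 0, 0, 0, 1, 1, 1, 1]),
        partition_topology([0, 1, 0, 1, 0, 1, 0, 1]),
    ]


@pytest.fixture(scope="session")
def stationary_segment(two_topologies):
    """Single-topology, noise-free coupling: a stationary network fixture."""
    return gen_switching_segment(
        [two_topologies[0]], dwell_mean_s=2.0, dwell_cv=0.3,
        freqs=(10.0,), snr=np.inf, seed=11,
    )


@pytest.fixture(scope="session")
def switching_segment(two_topologies):
    """Two-topology fixture switching every ~2 s."""
    return gen_switching_segment(
        two_topologies, dwell_mean_s=2.0, dwell_cv=0.3,
        freqs=(10.0,), snr=np.inf, seed=12,
    )


@pytest.fixture(scope="session")
def wavelet_10hz():
    return WaveletConfig(freqs=(10.0,))


@pytest.fixture
def sinusoid_segment():
    """Unit 10-Hz sinusoid, one channel, 10 s at 250 Hz."""
    t = np.arange(2500) / 250.0
    x = np.cos(2 * np.pi * 10.0 * t)[None, :]
    return Segment(x - x.mean(), 250.0, ("Cz",))
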