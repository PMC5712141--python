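import numpy as np
import pytest

from gaitassist.synthetic_gait import SimConfig, simulate_session
from gaitassist.timeseries_io import SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def track_factory():
    def make(samples, fs=60.0, t0=0.0):
        return SignalTrack(np.asarray(samples, dtype=float), fs, t0)

    return make


@pytest.fixture
def synthetic_session():
    """Default-config session, seed 1 (recording + ground-truth annotations)."""
    return simulate_session(SimConfig(seed=1))


def random_accel_tracks(rng, n, fs):
    """Random gait-like 3-axis record used by the oracle equivalence tests."""
    t = np.arange(n) / fs
    freq = rng.uniform(0.8, 2.5)
    ax = rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * freq * t) + rng.normal(0, 0.3, n)
    ay = rng.uniform(0.2, 1.0) * np.cos(2 * np.pi * freq * t) + rng.normal(0, 0.3, n)
    az = 9.81 + rng.uniform(0.5, 2.0) * np.sin(4 * np.pi * freq * t) + rng.normal(0, 0.3, n)
    # a couple of sustained excursions so detections actually occur
    for _ in range(rng.integers(0, 3)):
        i0 = rng.integers(0, max(n - 1, 1))
        width = int(rng.uniform(0.5, 2.0) * fs)
        az[i0 : i0 + width] += rng.uniform(3.0, 20.0)
    return (
        SignalTrack(ax, fs),
        SignalTrack(ay, fs),
        SignalTrack(az, fs),
    )
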