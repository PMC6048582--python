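import numpy as np
import pytest

from wavebispec import MorletParams, ScaleGrid, Signal, build_bifreq_grid, make_scale_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """16-scale log grid, 100-600 Hz, for fs >= 1200 Hz signals."""
    return make_scale_grid(100.0, 600.0, 16, 5512.0)


@pytest.fixture
def triplet_grid():
    """Explicit grid containing the 160/320/480 Hz triplet exactly."""
    freqs = [110.0, 135.0, 160.0, 200.0, 260.0, 320.0, 400.0, 480.0, 560.0]
    return ScaleGrid.from_frequencies(freqs, MorletParams())


@pytest.fixture
def random_signal(rng):
    def make(n=1024, fs=2048.0):
        return Signal(samples=rng.standard_normal(n), fs=fs)

    return make
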