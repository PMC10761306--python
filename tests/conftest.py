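import numpy as np
import pytest

from needletrack.simdata import SimConfig, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_pair():
    """Noiseless 64x64 pair: no speckle, dropout, ghosts or PA artifacts."""
    cfg = SimConfig(
        image_size=(64, 64),
        speckle_scale=0.0,
        needle_dropout=0.0,
        echo_ghost_count=0,
        pa_artifact_count=0,
        seed=7,
    )
    return simulate_pair(cfg)


@pytest.fixture(scope="session")
def noisy_pair():
    """Default-degradation 128x128 pair."""
    return simulate_pair(SimConfig(image_size=(128, 128), seed=3))


def make_tone_rf(n_samples=512, n_lines=4, fs=40.0, fc=8.0, amplitude=1.0):
    """RF frame of a pure carrier tone on every line (MHz units)."""
    t = np.arange(n_samples) / fs
    line = amplitude * np.cos(2 * np.pi * fc * t)
    return np.tile(line[:, None], (1, n_lines)), fs, fc
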