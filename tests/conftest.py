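import numpy as np
import pytest

import painsense as ps


@pytest.fixture(scope="session")
def small_recording():
    """A 6-channel recording with 12 events and a strong alpha effect."""
    cfg = ps.SimulationConfig(
        n_channels=6, fs=500.0, n_events=12,
        band_effect={"alpha": 3.0, "beta": 1.0}, seed=7,
    )
    raw, events = ps.generate_recording(cfg)
    return cfg, raw, events


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    _, raw, events = small_recording
    return ps.epoch(raw, events)


@pytest.fixture(scope="session")
def separable_table():
    """Two well-separated classes: 60 + 60 samples, 20 features."""
    fm, labels = ps.generate_feature_table((60, 60), 20, effect_size=6.0, seed=3)
    return fm, labels


@pytest.fixture
def rng():
    return np.random.default_rng(0)
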