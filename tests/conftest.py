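import numpy as np
import pytest

from tinnigraph.preprocess import apply_filter, define_events, design_bandpass, make_epochs
from tinnigraph.synth import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A 20 s, 16-channel recording config: fast but structurally realistic."""
    return SynthConfig(n_subjects_per_class=3, duration=20.0, seed=42)


@pytest.fixture(scope="session")
def clean_recording(small_config):
    return generate_recording(small_config, class_label=0, seed=7)


@pytest.fixture(scope="session")
def bandpass(small_config):
    return design_bandpass(4, 1.0, 40.0, fs=small_config.fs)


@pytest.fixture(scope="session")
def clean_epochs(clean_recording, bandpass):
    filtered = apply_filter(clean_recording, bandpass)
    return make_epochs(filtered, define_events(filtered), 0.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
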