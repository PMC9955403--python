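import numpy as np
import pytest

from cghofd import (
    SynthFeatureConfig,
    SynthWaveformConfig,
    generate_feature_table,
    generate_waveforms,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_waveforms():
    """Noise-free 20 s record with ground truth."""
    return generate_waveforms(SynthWaveformConfig(duration_s=20, fs=125,
                                                  noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_waveforms():
    """Low-noise 20 s record with ground truth."""
    return generate_waveforms(SynthWaveformConfig(duration_s=20, fs=125,
                                                  noise_sd=0.001, seed=7))


@pytest.fixture(scope="session")
def sparse_table():
    """Feature table with known support {0,1,2} out of 10 features, n=400."""
    return generate_feature_table(SynthFeatureConfig(
        n_segments=400, n_features=10, support=(0, 1, 2),
        effect_sizes=(8.0, 6.0, 4.0), noise_sd=2.0, seed=42))


@pytest.fixture(scope="session")
def small_table():
    """Feature table with support {0,1} + 6 noise features, n=300."""
    return generate_feature_table(SynthFeatureConfig(
        n_segments=300, n_features=8, support=(0, 1),
        effect_sizes=(5.0, 3.0), noise_sd=1.0, seed=11))
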