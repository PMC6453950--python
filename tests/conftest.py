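import numpy as np
import pytest

from axonwave.detection import DetectionSettings
from axonwave.sequences import detect_sequences
from axonwave.synthetic import SyntheticConfig, generate_clean, generate_dataset


@pytest.fixture(scope="session")
def clean_ds():
    """Noiseless default dataset: 40 sequences over 1 s at 0.5 m/s."""
    return generate_clean(SyntheticConfig())


@pytest.fixture(scope="session")
def clean_seqs(clean_ds):
    with np.errstate(all="ignore"):
        return detect_sequences(clean_ds.channel_group(), DetectionSettings(5.0))


@pytest.fixture(scope="session")
def noisy_ds():
    """Moderate-noise dataset (SNR 0.5, 5 s) used by several stochastic tests."""
    return generate_dataset(SyntheticConfig(snr=0.5, duration=5.0), seed=7)


@pytest.fixture(scope="session")
def noisy_seqs(noisy_ds):
    return detect_sequences(noisy_ds.channel_group(), DetectionSettings(2.2))
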