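import numpy as np
import pytest

from semg import ClassSignature


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def narrowband_signature():
    """Single-channel signature: 80 Hz center, 40 Hz bandwidth, clean."""
    return ClassSignature(
        centers=[80.0], bandwidths=[40.0], envelopes=[(0.1, 0.8, 0.1)],
        amplitudes=[1.0], noise_sd=0.0, channel_names=("X",),
    )


@pytest.fixture
def four_channel_signature():
    return ClassSignature(
        centers=[80.0, 150.0, 220.0, 300.0],
        bandwidths=[40.0, 40.0, 60.0, 60.0],
        envelopes=[(0.1, 0.8, 0.1)] * 4,
        amplitudes=[1.0, 0.8, 1.2, 0.9],
        noise_sd=0.05,
    )
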