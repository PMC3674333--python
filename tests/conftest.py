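import numpy as np
import pytest

from muerd.layout import default_egi128_layout, minimal_layout
from muerd.preprocess import EpochSet


@pytest.fixture(scope="session")
def layout128():
    return default_egi128_layout()


@pytest.fixture(scope="session")
def layout21():
    return minimal_layout()


def make_epochset(data, sfreq, channel_ids=None, condition=None, source_offset=1000):
    """EpochSet from an (n_epochs, n_channels, n_samples) array with
    synthetic provenance (all epochs from trial 0, offset into a source)."""
    data = np.asarray(data, dtype=float)
    n_e, _, n_s = data.shape
    onsets = np.arange(n_e) * n_s
    return EpochSet(
        epochs=data,
        sfreq=sfreq,
        channel_ids=list(channel_ids) if channel_ids is not None else list(range(1, data.shape[1] + 1)),
        onsets=onsets,
        source_trials=np.zeros(n_e, dtype=int),
        source_onsets=onsets + source_offset,
        epoch_length_s=n_s / sfreq,
        condition=condition,
    )
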