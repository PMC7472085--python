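import numpy as np
import pandas as pd
import pytest

from emochart.containers import Recording, SegmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eeg_recording(rng):
    """Random 14-channel, 10-s EEG recording at 128 Hz."""
    return Recording(rng.standard_normal((14, 10 * 128)), 128, "EEG", 3, 7)


def make_segment_set(data, labels=None, modality="EEG", normalized=False):
    n = len(data)
    prov = pd.DataFrame({"subject": 0, "trial": 0, "segment": np.arange(n)})
    if labels is None:
        labels = np.zeros(n, dtype=int)
    return SegmentSet(np.asarray(data), labels, prov, modality, normalized)
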