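import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seizformer as sz

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_subject() -> sz.EEGRecord:
    """A 240-s, 16-channel synthetic subject with a handful of seizures."""
    return sz.make_subject(sz.SimConfig(
        duration_s=240.0, seizure_rate=4, seizure_len_s=(15.0, 30.0), seed=3))


@pytest.fixture(scope="session")
def labeled_windows(short_subject) -> sz.WindowSet:
    rec = sz.bandpass(short_subject)
    ws = sz.segment_windows(rec, window_s=1.0, overlap=0.5)
    return sz.label_windows(ws, rec.seizure_intervals)


def make_record(data: np.ndarray, fs: float = 256.0,
                intervals=None) -> sz.EEGRecord:
    labels = [f"CH{i:02d}-REF" for i in range(data.shape[0])]
    return sz.EEGRecord(data=data, fs=fs, channel_labels=labels,
                        seizure_intervals=intervals or [])
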