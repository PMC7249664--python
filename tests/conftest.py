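import numpy as np
import pytest

from drivestress import synthetic_data as sd
from drivestress.core import Channel


@pytest.fixture(scope="session")
def track():
    return sd.make_default_track()


@pytest.fixture(scope="session")
def manual_session(track):
    """One default manual session at the fast SPR-analysis rate (no ECG)."""
    return sd.generate_session("s01", "manual", track, fs=50.0, seed=42, n_ecg=0)


@pytest.fixture(scope="session")
def ecg_session(track):
    """One manual session at an ECG-capable sampling rate."""
    return sd.generate_session("s01", "manual", track, fs=250.0, seed=42, n_ecg=3)


def make_channel(samples, fs=50.0, name="x", unit="mV"):
    return Channel(name, unit, fs, np.asarray(samples, dtype=float))


@pytest.fixture
def channel_factory():
    return make_channel
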