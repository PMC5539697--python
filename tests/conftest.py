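"""Shared fixtures: small synthetic subjects kept cheap enough for unit tests."""

import numpy as np
import pytest

import sleepfusion as sf


@pytest.fixture(scope="session")
def small_subject():
    """One 120-epoch (1-h) subject with a programmed 20-epoch absence."""
    profile = sf.SubjectProfile(seed=5, absence_intervals=((60, 80),))
    return sf.simulate_subject(120, profile=profile, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Three 120-epoch subjects for train/classify smoke tests."""
    return sf.simulate_cohort(3, 120, seed=11)


@pytest.fixture(scope="session")
def quiet_epoch_bands(small_subject):
    """Band decomposition of a quiet breathing (NREM, no movement) epoch."""
    channel, _ = sf.select_channel(small_subject.recording)
    epochs = sf.frame_signal(channel)
    stages = small_subject.hypnogram.stages
    idx = int(np.flatnonzero(stages == sf.NREM)[3])
    epoch = epochs.data[idx].astype(np.float64)
    return epoch, sf.bandpass_decompose(epoch)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
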