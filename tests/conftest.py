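"""Shared fixtures: small synthetic objects reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from voicersa import synthetic as syn
from voicersa.containers import EpochArray


@pytest.fixture(scope="session")
def stimuli16():
    """Desk-scale stimulus set: 8 speakers x 2 vowels = 16 stimuli."""
    return syn.make_stimulus_set(8, ("a", "i"))


@pytest.fixture(scope="session")
def space2(stimuli16):
    return syn.generate_latent_space(8, 2, syn.default_loading_spec(2), seed=11)


@pytest.fixture(scope="session")
def design16(stimuli16):
    return syn.generate_design(stimuli16, n_repetitions=10, seed=11)


@pytest.fixture(scope="session")
def epochs16(design16, space2, stimuli16):
    """Small EEG set with an embedded effect at 100-300 ms (16 channels)."""
    truth = syn.SyntheticTruth(effect_windows=((100.0, 300.0), (150.0, 350.0)), snr=1.0, seed=11)
    return syn.generate_eeg(
        design16, space2, truth, stimuli16, n_channels=16, sfreq=100.0
    )


@pytest.fixture(scope="session")
def ratings16(space2, stimuli16):
    return syn.generate_ratings(space2, stimuli16, n_raters=12, seed=11)


def make_epochs(data, sfreq=100.0, tmin=-100.0, labels=None, positions=None, meta=None):
    """Tiny EpochArray factory for hand-constructed data."""
    n_trials, n_ch, n_t = data.shape
    times = tmin + np.arange(n_t) * 1000.0 / sfreq
    if labels is None:
        labels, positions = syn.standard_montage(max(n_ch, 14))
        labels, positions = labels[:n_ch], positions[:n_ch]
    if meta is None:
        meta = pd.DataFrame(
            {
                "stimulus_id": [f"s{i % 4}" for i in range(n_trials)],
                "trial_type": "experimental",
                "keep_flag": True,
            }
        )
    return EpochArray(
        data=data,
        times=times,
        channel_labels=list(labels),
        channel_positions=positions,
        trial_meta=meta,
    )
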