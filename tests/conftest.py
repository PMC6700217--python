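import numpy as np
import pandas as pd
import pytest

from corticolfp.classify import CohortTable
from corticolfp.preprocessing import EpochSet
from corticolfp.recording import CHANNELS, RawRecording
from corticolfp.spectral import feature_names
from corticolfp.synthetic import SubjectSpec, generate_recording


@pytest.fixture(scope="session")
def quiet_spec():
    """Subject with a low pink-noise floor so band effects dominate."""
    return SubjectSpec(subject_id="quiet", background_rms=0.02)


@pytest.fixture(scope="session")
def clean_recording():
    """30 s baseline 4-channel recording at 2 kHz."""
    spec = SubjectSpec(subject_id="base")
    return generate_recording(spec, duration=30.0, fs=2000.0, seed=42)


def make_tone_recording(freq, duration=30.0, fs=2000.0, amplitude=1.0, n_channels=4):
    """Pure sinusoid on every channel (helper, not a fixture)."""
    t = np.arange(int(duration * fs)) / fs
    tone = amplitude * np.sin(2 * np.pi * freq * t)
    return RawRecording(
        samples=np.tile(tone, (n_channels, 1)),
        fs=fs,
        channel_labels=CHANNELS[:n_channels],
        subject_id="tone",
    )


def make_noise_epochs(seed, n_epochs=10, epoch_length=3.0, fs=400.0, n_channels=2,
                      labels=("lNAcSh", "rNAcSh")):
    """Independent white-noise epochs (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    n = int(epoch_length * fs)
    eps = [rng.standard_normal((n_channels, n)) for _ in range(n_epochs)]
    return EpochSet(
        epochs=eps,
        epoch_length=epoch_length,
        fs=fs,
        channel_labels=labels[:n_channels],
    )


def make_noise_table(seed, n_subjects=13, n_features=60, n_hd=None):
    """Feature table with no class signal, labeled n_hd/rest."""
    if n_hd is None:
        n_hd = (n_subjects + 1) // 2
    rng = np.random.default_rng(seed)
    idx = [f"rat{i:02d}" for i in range(n_subjects)]
    cols = feature_names()[:n_features]
    if len(cols) < n_features:
        cols = [f"f{i}" for i in range(n_features)]
    X = pd.DataFrame(rng.standard_normal((n_subjects, n_features)), index=idx, columns=cols)
    lab = pd.Series(["HD"] * n_hd + ["LD"] * (n_subjects - n_hd), index=idx)
    return CohortTable(features=X, labels=lab)
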