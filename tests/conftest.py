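import numpy as np
import pytest

from envtrf.containers import AudioStimulus, EEGRecording, LagSpec
from envtrf.synth import SyntheticCohortSpec, make_cohort


@pytest.fixture(scope="session")
def lags128() -> LagSpec:
    return LagSpec(fs=128.0)


@pytest.fixture(scope="session")
def tone_1khz() -> AudioStimulus:
    fs = 22050.0
    t = np.arange(int(2 * fs)) / fs
    return AudioStimulus(samples=0.5 * np.sin(2 * np.pi * 1000.0 * t), fs=fs, track_id="tone")


@pytest.fixture(scope="session")
def am_noise() -> AudioStimulus:
    """Amplitude-modulated noise: broadband carrier, 4 Hz modulation."""
    rng = np.random.default_rng(7)
    fs = 22050.0
    n = int(8 * fs)
    t = np.arange(n) / fs
    carrier = rng.standard_normal(n)
    wave = carrier * (1.0 + 0.8 * np.sin(2 * np.pi * 4.0 * t))
    return AudioStimulus(samples=0.9 * wave / np.abs(wave).max(), fs=fs, track_id="am")


@pytest.fixture(scope="session")
def noiseless_cohort():
    """1 subject, noise-free: the kernel-recovery workhorse (small tracks)."""
    spec = SyntheticCohortSpec(
        n_subjects=1, n_tracks=3, track_duration_s=15.0, noise_sd=0.0,
        between_subject_sd=0.0, between_session_sd=0.0, seed=11,
    )
    return make_cohort(spec)


@pytest.fixture()
def noise_recording() -> EEGRecording:
    """Continuous white-noise recording with three epochs at 128 Hz."""
    rng = np.random.default_rng(3)
    fs = 128.0
    n_pre = int(6 * fs)
    n_track = int(10 * fs)
    n = 3 * (n_pre + n_track) + n_pre
    data = rng.standard_normal((12, n))
    onsets = [n_pre + i * (n_pre + n_track) for i in range(3)]
    labels = [f"ch{i:02d}" for i in range(12)]
    return EEGRecording(
        data=data, fs=fs, channel_labels=labels,
        mastoid_channels=(labels[0], labels[-1]),
        epochs=[(o, f"t{i}") for i, o in enumerate(onsets)],
    )
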