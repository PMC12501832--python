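"""Synthetic speech-like stimuli and two-session EEG with known ground truth.

The generator emulates a two-session continuous-speech EEG study: every
subject hears the same set of ~65 s tracks in both sessions, and the EEG
is produced by the forward model that the estimation side assumes —

    eeg_c[t] = topo_c * (kernel * envelope)[t] + pink noise

* **Stimulus**: amplitude-modulated pink noise; the modulator is a
  rectified sum of sinusoids at 3-5 Hz with random phases, so the
  envelope carries its energy at syllabic rates (2-8 Hz), where natural
  speech envelopes are strongest.
* **Ground-truth kernel**: a difference of two gamma pulses with a
  positive deflection near 50-100 ms and a negative one near 150-250 ms,
  supported on [0, 500] ms.  Per-subject and per-session variability act
  multiplicatively on the kernel amplitude only (latencies are fixed), so
  the between/within variance structure of downstream measures is
  controlled by two dials: ``between_subject_sd`` and
  ``between_session_sd``.
* **Topography**: a fixed raised-cosine spatial profile peaking at a
  designated vertex ("Cz") channel, giving the frontocentral emphasis
  typical of auditory responses without modelling head geometry.
* **Noise**: 1/f-shaped (pink) noise, independent across channels, with
  SD ``noise_sd``.

Tracks are laid out in a continuous recording with 6 s noise-only gaps so
that the -5..0 s pre-stimulus window needed for SNR estimation exists for
every epoch.  Generation is a pure function of the spec, including the
seed: identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal import fftconvolve

from .containers import AudioStimulus, EEGRecording, LagSpec
from .features import broadband_envelope

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruth",
    "Cohort",
    "make_stimulus",
    "make_ground_truth_kernel",
    "kernel_topography",
    "simulate_session",
    "make_cohort",
]

# spawn-key stage tags for deterministic, independent substreams
_STAGE_STIMULUS = 0
_STAGE_SUBJECT = 1
_STAGE_SESSION = 2
_STAGE_NOISE = 3

_GAP_S = 6.0  # noise-only gap before each track (covers the -5 s baseline)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 8
    n_tracks: int = 6
    track_duration_s: float = 65.0
    fs_audio: float = 22050.0
    fs_eeg: float = 128.0
    n_channels: int = 64
    kernel_family: str = "gamma-difference"
    between_subject_sd: float = 0.15
    between_session_sd: float = 0.05
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 3:
            raise ValueError("need n_tracks >= 3 (minimum for leave-one-track-out CV)")
        if self.track_duration_s <= 0:
            raise ValueError("track_duration_s must be positive")
        if min(self.between_subject_sd, self.between_session_sd, self.noise_sd) < 0:
            raise ValueError("variance dials must be non-negative")
        if self.kernel_family != "gamma-difference":
            raise ValueError(f"unknown kernel family {self.kernel_family!r}")

    def rng(self, *key: int) -> np.random.Generator:
        """Named substream: independent of all other (stage, ...) keys."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))


@dataclass
class GroundTruth:
    """Generative kernels retained for recovery tests.

    ``temporal`` holds the per-subject, per-session kernel time course on
    ``lag_axis_ms`` (support [0, 500] ms); the full lags x channels kernel
    for subject i, session s is ``outer(temporal[i, s-1], topography)``.
    """

    temporal: np.ndarray        # (n_subjects, 2, n_kernel_lags)
    topography: np.ndarray      # (n_channels,)
    lag_axis_ms: np.ndarray
    cz_index: int

    def kernel(self, subject: int, session: int) -> np.ndarray:
        return np.outer(self.temporal[subject, session - 1], self.topography)

    def on_lag_axis(self, lags: LagSpec, subject: int, session: int) -> np.ndarray:
        """Kernel embedded in a TRF lag axis (zeros outside [0, 500] ms)."""
        out = np.zeros((lags.n_lags, self.topography.size))
        kern = self.kernel(subject, session)
        for j, l in enumerate(np.round(self.lag_axis_ms * lags.fs / 1000.0).astype(int)):
            pos = l - lags.lag_min
            if 0 <= pos < lags.n_lags:
                out[pos] += kern[j]
        return out


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    stimuli: list[AudioStimulus]
    recordings: dict[tuple[int, int], EEGRecording] = field(default_factory=dict)
    ground_truth: GroundTruth | None = None


def _pink_noise(rng: np.random.Generator, n: int, fs: float, n_channels: int | None = None) -> np.ndarray:
    """1/f-amplitude noise, unit SD per channel (last axis = time)."""
    shape = (n,) if n_channels is None else (n_channels, n)
    white = rng.standard_normal(shape)
    freqs = rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0
    x = irfft(rfft(white, axis=-1) * shaping, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def make_stimulus(duration_s: float, fs_audio: float, seed, track_id: str = "track") -> AudioStimulus:
    """Speech-like track: pink-noise carrier, syllabic-rate amplitude modulation.

    The modulator is a half-wave rectified sum of four sinusoids with
    frequencies drawn uniformly in 3-5 Hz and random phases, placing the
    envelope modulation-spectrum peak between 2 and 8 Hz.  Output is
    scaled to peak amplitude 0.95.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_audio < 16000:
        raise ValueError("fs_audio must be at least 16 kHz to cover the 250-8000 Hz band")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_audio))
    t = np.arange(n) / fs_audio
    freqs = rng.uniform(3.0, 5.0, size=4)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    amps = rng.uniform(0.5, 1.0, size=4)
    mod = np.clip(sum(a * np.sin(2 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases)), 0.0, None)
    carrier = _pink_noise(rng, n, fs_audio)
    wave = carrier * (0.15 + mod)
    wave *= 0.95 / np.max(np.abs(wave))
    return AudioStimulus(samples=wave, fs=fs_audio, track_id=track_id)


def _gamma_pulse(t_ms: np.ndarray, shape: float, scale_ms: float) -> np.ndarray:
    """Gamma-shaped pulse normalised to unit peak (t in ms, zero for t < 0)."""
    t = np.clip(t_ms, 0.0, None)
    g = t ** (shape - 1.0) * np.exp(-t / scale_ms)
    peak = ((shape - 1.0) * scale_ms) ** (shape - 1.0) * np.exp(-(shape - 1.0))
    return g / peak


def _base_kernel(fs_eeg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude difference-of-gammas kernel on [0, 500] ms."""
    n = int(round(0.5 * fs_eeg)) + 1
    t_ms = np.arange(n) * 1000.0 / fs_eeg
    kern = _gamma_pulse(t_ms, 3.0, 40.0) - 0.7 * _gamma_pulse(t_ms, 4.0, 60.0)
    # cosine taper over the last 100 ms forces the support to end at 500 ms
    taper = np.ones_like(t_ms)
    tail = t_ms >= 400.0
    taper[tail] = 0.5 * (1.0 + np.cos(np.pi * (t_ms[tail] - 400.0) / 100.0))
    return t_ms, kern * taper


def kernel_topography(n_channels: int, cz_index: int | None = None) -> np.ndarray:
    """Raised-cosine spatial profile peaking at the vertex channel."""
    if cz_index is None:
        cz_index = n_channels // 2
    idx = np.arange(n_channels)
    radius = max(n_channels / 2.0, 1.0)
    w = 0.5 * (1.0 + np.cos(np.pi * np.clip(np.abs(idx - cz_index) / radius, 0.0, 1.0)))
    return 0.1 + 0.9 * w


def _subject_gain(spec: SyntheticCohortSpec, subject: int) -> float:
    g = 1.0 + spec.between_subject_sd * spec.rng(_STAGE_SUBJECT, subject).standard_normal()
    return max(g, 0.1)


def _session_gain(spec: SyntheticCohortSpec, subject: int, session: int) -> float:
    if session == 1:
        return 1.0
    g = 1.0 + spec.between_session_sd * spec.rng(_STAGE_SESSION, subject, session).standard_normal()
    return max(g, 0.1)


def make_ground_truth_kernel(spec: SyntheticCohortSpec, subject: int, session: int) -> np.ndarray:
    """Lags x channels kernel for one subject and session.

    Session 1 is the per-subject baseline (amplitude 1 + between-subject
    draw); session 2 multiplies it by 1 + a between-session draw.  With
    both SDs zero all kernels are identical.
    """
    if not 0 <= subject < spec.n_subjects:
        raise IndexError("subject index out of range")
    if session not in (1, 2):
        raise IndexError("session must be 1 or 2")
    _, kern = _base_kernel(spec.fs_eeg)
    amp = _subject_gain(spec, subject) * (
        _session_gain(spec, subject, 2) if session == 2 else 1.0
    )
    topo = kernel_topography(spec.n_channels)
    return np.outer(amp * kern, topo)


def _track_layout(spec: SyntheticCohortSpec) -> tuple[int, list[int]]:
    """Total samples and per-track onset samples with leading gaps."""
    n_gap = int(round(_GAP_S * spec.fs_eeg))
    onsets = []
    pos = 0
    for _ in range(spec.n_tracks):
        pos += n_gap
        onsets.append(pos)
        pos += int(round(spec.track_duration_s * spec.fs_eeg))
    pos += n_gap
    return pos, onsets


def _envelopes(stimuli: list[AudioStimulus], fs_eeg: float) -> list[np.ndarray]:
    return [broadband_envelope(s, fs_out=fs_eeg).values[:, 0] for s in stimuli]


def simulate_session(
    stimuli: list[AudioStimulus],
    kernel: np.ndarray,
    spec: SyntheticCohortSpec,
    subject: int = 0,
    session: int = 1,
    envelopes: list[np.ndarray] | None = None,
) -> EEGRecording:
    """Forward-simulate one continuous recording from a lags x channels kernel.

    Per track the signal is the causal discrete convolution of the
    broadband envelope with the kernel; tracks are separated by
    noise-only gaps and onset events are recorded.  ``envelopes`` may be
    passed to reuse precomputed broadband envelopes.
    """
    if not stimuli:
        raise ValueError("empty stimulus list")
    if len(stimuli) != spec.n_tracks:
        raise ValueError("stimulus count must match spec.n_tracks")
    if envelopes is None:
        envelopes = _envelopes(stimuli, spec.fs_eeg)
    n_total, onsets = _track_layout(spec)
    n_track = int(round(spec.track_duration_s * spec.fs_eeg))
    data = np.zeros((spec.n_channels, n_total))
    if np.any(kernel):
        for onset, env in zip(onsets, envelopes):
            sig = fftconvolve(env[:n_track, None], kernel, axes=0)[:n_track]
            data[:, onset : onset + n_track] += sig.T
    if spec.noise_sd > 0:
        rng = spec.rng(_STAGE_NOISE, subject, session)
        data += spec.noise_sd * _pink_noise(rng, n_total, spec.fs_eeg, spec.n_channels)
    labels = [f"ch{i:02d}" for i in range(spec.n_channels)]
    return EEGRecording(
        data=data,
        fs=spec.fs_eeg,
        channel_labels=labels,
        mastoid_channels=(labels[0], labels[-1]),
        subject_id=f"s{subject:02d}",
        session=session,
        epochs=[(onset, stim.track_id) for onset, stim in zip(onsets, stimuli)],
    )


def spec_for_accuracy_icc(
    ratio: float,
    amplitude_jitter: float = 0.15,
    **kwargs,
) -> SyntheticCohortSpec:
    """Cohort spec whose accuracy-scale variance ratio targets ``ratio``.

    Session 1 carries only the between-subject amplitude draw and session
    2 multiplies it by the session draw, so the within-subject variance
    component on any measure that is locally linear in kernel amplitude is
    ``between_session_sd**2 / 2``.  For a target ratio rho =
    sigma_b^2 / (sigma_b^2 + sigma_w^2) with overall amplitude jitter
    ``s`` this gives

        between_subject_sd = s * sqrt(rho)
        between_session_sd = s * sqrt(2 * (1 - rho))

    The mapping from amplitude to prediction accuracy is approximately
    linear for jitter of this size, and the cross-validation measurement
    noise of the channel-mean accuracy is an order of magnitude below the
    designed spread, so the ratio carries to the accuracy scale.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    return SyntheticCohortSpec(
        between_subject_sd=amplitude_jitter * float(np.sqrt(ratio)),
        between_session_sd=amplitude_jitter * float(np.sqrt(2.0 * (1.0 - ratio))),
        **kwargs,
    )


def make_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Full two-session cohort: recordings per (subject, session) + ground truth.

    All subjects and both sessions share the same stimuli (as when every
    participant hears the same audiobook twice).
    """
    stimuli = [
        make_stimulus(
            spec.track_duration_s,
            spec.fs_audio,
            seed=np.random.SeedSequence(spec.seed, spawn_key=(_STAGE_STIMULUS, t)),
            track_id=f"t{t:02d}",
        )
        for t in range(spec.n_tracks)
    ]
    envelopes = _envelopes(stimuli, spec.fs_eeg)
    t_ms, base = _base_kernel(spec.fs_eeg)
    topo = kernel_topography(spec.n_channels)
    temporal = np.empty((spec.n_subjects, 2, base.size))
    cohort = Cohort(spec=spec, stimuli=stimuli)
    for i in range(spec.n_subjects):
        amp1 = _subject_gain(spec, i)
        for s in (1, 2):
            amp = amp1 * (_session_gain(spec, i, 2) if s == 2 else 1.0)
            temporal[i, s - 1] = amp * base
            kernel = np.outer(temporal[i, s - 1], topo)
            cohort.recordings[(i, s)] = simulate_session(
                stimuli, kernel, spec, subject=i, session=s, envelopes=envelopes
            )
    cohort.ground_truth = GroundTruth(
        temporal=temporal,
        topography=topo,
        lag_axis_ms=t_ms,
        cz_index=spec.n_channels // 2,
    )
    return cohort
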