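"""Core data containers shared across the pipeline.

The containers are deliberately thin: plain ``dataclass`` wrappers around
numpy arrays plus the metadata tags (sampling rate, reference scheme,
analysis band, epoch bookkeeping) that the processing stages read and
update.  All sample indexing is 0-based and windows are half-open
``[start, stop)``; epoch times are seconds relative to track onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Stimulus feature kinds: broadband envelope, its temporal derivative,
#: 8-band gammatone (multiband) envelope, and its derivative.
FEATURE_KINDS = ("bbenv", "bbenv_deriv", "mbenv", "mbenv_deriv")

#: EEG analysis bands (Hz edges).  "wide" is the 1-15 Hz preprocessing band;
#: delta/theta/full are the TRF analysis bands.
BANDS = {"wide": (1.0, 15.0), "delta": (1.0, 4.0), "theta": (4.0, 8.0), "full": (1.0, 8.0)}

REFERENCES = ("raw", "avg_mastoid", "car")


@dataclass
class AudioStimulus:
    """Mono audio waveform for one ~65 s track."""

    samples: np.ndarray  # 1-D float array, amplitude in [-1, 1]
    fs: float            # audio sampling rate, Hz
    track_id: str = "track"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioStimulus is mono: samples must be 1-D")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class StimulusFeature:
    """Time x band stimulus representation at the EEG sampling rate."""

    values: np.ndarray           # (n_samples, n_bands)
    fs: float                    # Hz, matches downstream EEG rate
    kind: str                    # one of FEATURE_KINDS
    band_centers_hz: Sequence[float] = (0.0,)
    compression_exponent: float = 0.6
    zscored: bool = False
    track_id: str = "track"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < self.values.shape[1]:
            # accept (bands, time) input but store (time, bands)
            pass
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        n_bands = self.values.shape[1]
        expected = 1 if self.kind.startswith("bb") else 8
        if n_bands != expected:
            raise ValueError(f"{self.kind} expects {expected} band(s), got {n_bands}")

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class EEGRecording:
    """Continuous multichannel recording with epoch bookkeeping.

    ``epochs`` holds ``(onset_sample, track_id)`` pairs; onsets index into
    ``data`` columns at the current sampling rate and are remapped by
    resampling.
    """

    data: np.ndarray                     # (n_channels, n_samples)
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    mastoid_channels: tuple[str, str] | None = None
    reference: str = "raw"
    band: str = "raw"
    subject_id: str = "s00"
    session: int = 1
    epochs: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        if "data" not in kwargs:
            out.data = self.data.copy()
        out.channel_labels = list(self.channel_labels)
        out.epochs = list(kwargs.get("epochs", self.epochs))
        return out


@dataclass
class LagSpec:
    """Lag window for the lagged design matrix.

    Positive lags mean the stimulus leads the response.  Lag samples are
    obtained by symmetric rounding of ``t_ms * fs / 1000`` at both ends,
    e.g. -100..1000 ms at 128 Hz gives lags -13..128 (142 lags).
    """

    tmin_ms: float = -100.0
    tmax_ms: float = 1000.0
    fs: float = 128.0

    def __post_init__(self) -> None:
        if not self.tmin_ms < self.tmax_ms:
            raise ValueError("tmin_ms must be < tmax_ms")

    @property
    def lag_min(self) -> int:
        return int(round(self.tmin_ms * self.fs / 1000.0))

    @property
    def lag_max(self) -> int:
        return int(round(self.tmax_ms * self.fs / 1000.0))

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.lag_min, self.lag_max + 1)

    @property
    def n_lags(self) -> int:
        return self.lag_max - self.lag_min + 1

    @property
    def lag_axis_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


@dataclass
class TRFModel:
    """Estimated temporal response function (forward model)."""

    weights: np.ndarray        # (n_lags, n_bands, n_channels)
    bias: np.ndarray           # (n_channels,)
    lam: float                 # ridge parameter used
    lag_axis_ms: np.ndarray
    feature_kind: str = "bbenv"
    band: str = "raw"
    reference: str = "raw"

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]


@dataclass
class PredictionAccuracy:
    """Per-fold, per-channel held-out Pearson correlations."""

    r_per_fold: np.ndarray               # (n_folds, n_channels), NaN = undefined fold
    chance_samples: np.ndarray | None = None  # (n_perm, n_channels)

    @property
    def mean_r(self) -> np.ndarray:
        """Arithmetic mean over folds per channel (NaN folds excluded)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN channel -> NaN
            return np.nanmean(self.r_per_fold, axis=0)

    @property
    def chance_mean(self) -> np.ndarray | None:
        if self.chance_samples is None:
            return None
        return self.chance_samples.mean(axis=0)

    @property
    def n_folds(self) -> int:
        return self.r_per_fold.shape[0]
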