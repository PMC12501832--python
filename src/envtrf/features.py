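"""Stimulus feature extraction: speech-envelope representations at the EEG rate.

Four representations of the acoustic stimulus are supported, all sampled at
the EEG rate (128 Hz by default):

* ``bbenv`` — broadband envelope: band-limit the audio to 250-8000 Hz,
  take the magnitude of the analytic (Hilbert) signal, and compress with a
  0.6 power law (an approximation to cochlear compression).
* ``bbenv_deriv`` — first temporal derivative of the broadband envelope,
  emphasising acoustic edges (onsets/offsets of syllables and phonemes).
* ``mbenv`` — multiband envelope: the same envelope operation applied in
  each of eight gammatone bands whose centre frequencies are evenly spaced
  on the ERB-number scale from 250 to 8000 Hz; each band is z-scored.
* ``mbenv_deriv`` — first temporal derivative of the multiband envelope.

Band-limiting for the broadband envelope uses a zero-phase 4th-order
Butterworth band-pass.  The gammatone bank uses the standard 4th-order
all-pole approximation with Glasberg-Moore ERB bandwidths.  Resampling to
the EEG rate is an anti-aliased polyphase resample applied after the power
compression.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .containers import AudioStimulus, StimulusFeature

__all__ = [
    "erb_number",
    "erb_number_inverse",
    "erb_bandwidth",
    "erb_center_frequencies",
    "broadband_envelope",
    "multiband_envelope",
    "temporal_derivative",
    "zscore_feature_set",
]


def erb_number(f_hz):
    """ERB-number (Cam) scale: 21.4 * log10(4.37 * f/1000 + 1)."""
    f_hz = np.asarray(f_hz, dtype=float)
    return 21.4 * np.log10(4.37 * f_hz / 1000.0 + 1.0)


def erb_number_inverse(erb):
    """Inverse of :func:`erb_number` (Hz)."""
    erb = np.asarray(erb, dtype=float)
    return (10.0 ** (erb / 21.4) - 1.0) * 1000.0 / 4.37


def erb_bandwidth(fc_hz):
    """Equivalent rectangular bandwidth at centre frequency ``fc`` (Hz)."""
    fc_hz = np.asarray(fc_hz, dtype=float)
    return 24.7 * (4.37 * fc_hz / 1000.0 + 1.0)


def erb_center_frequencies(n: int = 8, lo: float = 250.0, hi: float = 8000.0) -> np.ndarray:
    """Centre frequencies equally spaced on the ERB-number scale.

    The first frequency equals ``lo`` and the last equals ``hi``.
    """
    if n < 2:
        raise ValueError("need at least 2 bands")
    if not 0 < lo < hi:
        raise ValueError("require 0 < lo < hi")
    return erb_number_inverse(np.linspace(erb_number(lo), erb_number(hi), n))


def _analytic_magnitude(x: np.ndarray) -> np.ndarray:
    """|Hilbert transform| computed on a fast FFT length, then truncated."""
    n = x.shape[-1]
    nfft = next_fast_len(n)
    return np.abs(signal.hilbert(x, N=nfft)[..., :n])


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase resample along the last axis."""
    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def broadband_envelope(
    audio: AudioStimulus,
    lo: float = 250.0,
    hi: float = 8000.0,
    fs_out: float = 128.0,
    compression: float = 0.6,
    zscore: bool = False,
) -> StimulusFeature:
    """Broadband envelope of ``audio`` at ``fs_out``.

    Band-pass to [lo, hi] Hz (zero-phase 4th-order Butterworth), take the
    analytic-signal magnitude, compress with ``x**compression``, and
    resample to ``fs_out``.  Output is clipped at 0 (resampling ringing can
    produce tiny negative excursions).  By default the broadband envelope
    is left unscaled; set ``zscore=True`` to standardise it.
    """
    if audio.fs <= 2 * hi:
        raise ValueError(f"audio rate {audio.fs} Hz must exceed twice the upper band edge {hi} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=audio.fs, output="sos")
    band = signal.sosfiltfilt(sos, audio.samples)
    env = _analytic_magnitude(band) ** compression
    env = np.clip(_resample_to(env, audio.fs, fs_out), 0.0, None)
    if zscore:
        env = (env - env.mean()) / env.std()
    return StimulusFeature(
        values=env[:, None],
        fs=fs_out,
        kind="bbenv",
        band_centers_hz=((lo * hi) ** 0.5,),
        compression_exponent=compression,
        zscored=zscore,
        track_id=audio.track_id,
    )


def gammatone_filterbank(n: int = 8, lo: float = 250.0, hi: float = 8000.0, fs: float = 22050.0):
    """IIR (4th-order all-pole approximation) gammatone bank.

    Returns ``(centers_hz, list of (b, a))`` transfer functions at rate ``fs``.
    """
    centers = erb_center_frequencies(n, lo, hi)
    return centers, [signal.gammatone(fc, "iir", fs=fs) for fc in centers]


def multiband_envelope(
    audio: AudioStimulus,
    n_bands: int = 8,
    lo: float = 250.0,
    hi: float = 8000.0,
    fs_out: float = 128.0,
    compression: float = 0.6,
    zscore: bool = True,
) -> StimulusFeature:
    """Eight-band gammatone envelope of ``audio`` at ``fs_out``.

    Per band: gammatone filter, analytic-signal magnitude, 0.6 power
    compression, resample.  When ``zscore`` is True each band is
    standardised over this track; for multi-track stimuli use
    :func:`zscore_feature_set` to standardise over the whole track set so
    cross-validation folds share a scale.
    """
    if audio.fs <= 2 * hi:
        raise ValueError(f"audio rate {audio.fs} Hz must exceed twice the upper band edge {hi} Hz")
    centers, bank = gammatone_filterbank(n_bands, lo, hi, fs=audio.fs)
    bands = []
    for b, a in bank:
        filtered = signal.lfilter(b, a, audio.samples)
        env = _analytic_magnitude(filtered) ** compression
        bands.append(np.clip(_resample_to(env, audio.fs, fs_out), 0.0, None))
    values = np.stack(bands, axis=1)
    if zscore:
        values = (values - values.mean(axis=0)) / values.std(axis=0)
    return StimulusFeature(
        values=values,
        fs=fs_out,
        kind="mbenv",
        band_centers_hz=tuple(centers),
        compression_exponent=compression,
        zscored=zscore,
        track_id=audio.track_id,
    )


def temporal_derivative(feature: StimulusFeature, rectify: bool = False) -> StimulusFeature:
    """First temporal derivative of an envelope feature (units: envelope/s).

    Computed per band as the first difference scaled by the sampling rate,
    length-preserved by prepending a zero.  The derivative is signed by
    default; ``rectify=True`` half-wave rectifies it (onset envelope).
    """
    if feature.kind.endswith("_deriv"):
        raise ValueError("feature is already a derivative")
    diff = np.diff(feature.values, axis=0) * feature.fs
    values = np.vstack([np.zeros((1, feature.n_bands)), diff])
    if rectify:
        values = np.clip(values, 0.0, None)
    return StimulusFeature(
        values=values,
        fs=feature.fs,
        kind=feature.kind + "_deriv",
        band_centers_hz=feature.band_centers_hz,
        compression_exponent=feature.compression_exponent,
        zscored=feature.zscored,
        track_id=feature.track_id,
    )


def zscore_feature_set(features: list[StimulusFeature]) -> list[StimulusFeature]:
    """Standardise each band using statistics pooled over all tracks.

    Used for the multiband envelope so that every cross-validation fold
    shares one scale per band.
    """
    if not features:
        raise ValueError("empty feature list")
    stacked = np.concatenate([f.values for f in features], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero variance band; cannot z-score")
    out = []
    for f in features:
        out.append(
            StimulusFeature(
                values=(f.values - mean) / sd,
                fs=f.fs,
                kind=f.kind,
                band_centers_hz=f.band_centers_hz,
                compression_exponent=f.compression_exponent,
                zscored=True,
                track_id=f.track_id,
            )
        )
    return out


def compute_feature(
    audio: AudioStimulus,
    kind: str,
    fs_out: float = 128.0,
    zscore_mb: bool = False,
) -> StimulusFeature:
    """Compute one of the four stimulus representations by name.

    ``zscore_mb`` controls per-track z-scoring of the multiband envelope;
    leave False and use :func:`zscore_feature_set` for multi-track work.
    """
    if kind in ("bbenv", "bbenv_deriv"):
        base = broadband_envelope(audio, fs_out=fs_out)
    elif kind in ("mbenv", "mbenv_deriv"):
        base = multiband_envelope(audio, fs_out=fs_out, zscore=zscore_mb)
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    if kind.endswith("_deriv"):
        return temporal_derivative(base)
    return base
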