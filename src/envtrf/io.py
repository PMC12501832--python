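"""File formats: WAV audio, native array containers, EEGLAB .set ingestion.

The native container for recordings and features is a ``.npy`` array next
to a JSON sidecar holding the metadata (rate, labels, tags, epochs).
Audio goes through standard WAV files; stereo input is downmixed to mono
with a warning.  EEGLAB ``.set`` files (MATLAB structs) can be ingested
either through MNE when it is installed or through a small scipy-based
reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.io import loadmat, wavfile

from .containers import AudioStimulus, EEGRecording, StimulusFeature

__all__ = [
    "read_wav",
    "write_wav",
    "save_recording",
    "load_recording",
    "save_feature",
    "load_feature",
    "load_eeglab_set",
]


def read_wav(path) -> AudioStimulus:
    """Read a WAV file as a mono stimulus (stereo is averaged, with a warning)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo WAV downmixed to mono", stacklevel=2)
        data = data.mean(axis=1)
    return AudioStimulus(samples=data, fs=float(fs), track_id=Path(path).stem)


def write_wav(path, stimulus: AudioStimulus) -> None:
    wavfile.write(path, int(stimulus.fs), stimulus.samples.astype(np.float32))


def save_recording(directory, rec: EEGRecording, name: str = "recording") -> Path:
    """Write a recording as <name>.npy plus a JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", rec.data)
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "mastoid_channels": list(rec.mastoid_channels) if rec.mastoid_channels else None,
        "reference": rec.reference,
        "band": rec.band,
        "subject_id": rec.subject_id,
        "session": rec.session,
        "epochs": [[int(on), tid] for on, tid in rec.epochs],
    }
    sidecar = directory / f"{name}.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_recording(sidecar) -> EEGRecording:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    data = np.load(sidecar.with_suffix(".npy"))
    return EEGRecording(
        data=data,
        fs=meta["fs"],
        channel_labels=meta["channel_labels"],
        mastoid_channels=tuple(meta["mastoid_channels"]) if meta["mastoid_channels"] else None,
        reference=meta["reference"],
        band=meta["band"],
        subject_id=meta["subject_id"],
        session=meta["session"],
        epochs=[(int(on), tid) for on, tid in meta["epochs"]],
    )


def save_feature(directory, feat: StimulusFeature, name: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or f"{feat.track_id}_{feat.kind}"
    np.save(directory / f"{name}.npy", feat.values)
    meta = {
        "fs": feat.fs,
        "kind": feat.kind,
        "band_centers_hz": list(feat.band_centers_hz),
        "compression_exponent": feat.compression_exponent,
        "zscored": feat.zscored,
        "track_id": feat.track_id,
    }
    sidecar = directory / f"{name}.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_feature(sidecar) -> StimulusFeature:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    values = np.load(sidecar.with_suffix(".npy"))
    return StimulusFeature(
        values=values,
        fs=meta["fs"],
        kind=meta["kind"],
        band_centers_hz=tuple(meta["band_centers_hz"]),
        compression_exponent=meta["compression_exponent"],
        zscored=meta["zscored"],
        track_id=meta["track_id"],
    )


def _squeeze(x):
    return np.squeeze(np.asarray(x))


def load_eeglab_set(path, subject_id: str = "s00", session: int = 1) -> EEGRecording:
    """Ingest a continuous EEGLAB ``.set`` file into an :class:`EEGRecording`.

    Reads the MATLAB struct directly (data matrix, ``srate``,
    ``chanlocs`` labels and ``event`` latencies; 1-based latencies become
    0-based epoch onsets with the event type as track id).  MATLAB v7.3
    files fall back to MNE when it is installed.
    """
    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
        eeg = mat["EEG"] if "EEG" in mat else mat[next(k for k in mat if not k.startswith("_"))]
        data = np.atleast_2d(np.asarray(eeg.data, dtype=float))
        fs = float(_squeeze(eeg.srate))
        try:
            chanlocs = np.atleast_1d(eeg.chanlocs)
            labels = [str(c.labels) for c in chanlocs]
        except AttributeError:
            labels = [f"ch{i:02d}" for i in range(data.shape[0])]
        epochs = []
        try:
            for ev in np.atleast_1d(eeg.event):
                epochs.append((int(round(float(_squeeze(ev.latency)))) - 1, str(_squeeze(ev.type))))
        except AttributeError:
            pass
    except NotImplementedError:  # MATLAB v7.3 (HDF5) files
        import mne

        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
        data = raw.get_data()
        fs = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
        ann = raw.annotations
        epochs = [(int(round(on * fs)), str(desc)) for on, desc in zip(ann.onset, ann.description)]
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=labels,
        subject_id=subject_id,
        session=session,
        epochs=epochs,
    )
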