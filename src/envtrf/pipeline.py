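"""End-to-end orchestration: synthesize -> preprocess -> features -> TRF -> reliability.

A :class:`RunConfig` declares the cohort, the condition grid (stimulus
features x analysis bands x references), the lag window, the ridge grid
and the permutation/data-amount settings.  :func:`run_pipeline` executes
every condition and writes tidy CSV tables plus a JSON manifest under
``output_dir/<feature>/<band>/<reference>/``.

Randomness is fanned out from the single root seed through named
substreams per (stage, subject, session), so adding or removing
conditions never perturbs the others, and identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import FEATURE_KINDS, EEGRecording, LagSpec, StimulusFeature, TRFModel
from .features import compute_feature, temporal_derivative, zscore_feature_set
from .preprocess import (
    artifact_hook,
    band_filter,
    bandpass_1_15,
    detect_bad_channels,
    epoch,
    epoch_window,
    replace_channels,
    rereference,
    resample_eeg,
)
from .reliability import bland_altman, icc_a1, icc_by_data_amount, icc_timecourse
from .synth import Cohort, SyntheticCohortSpec, make_cohort
from .trf import (
    TrackSet,
    accuracy_vs_data_amount,
    cross_validate,
    default_lambda_grid,
    lag_matrix,
    permutation_null,
    select_lambda,
    zscore_eeg,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "validate_config",
    "cohort_features",
    "preprocess_recording",
    "build_trackset",
    "run_condition",
    "run_pipeline",
]

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Declarative configuration for a full synthetic run."""

    cohort: dict = field(default_factory=dict)  # SyntheticCohortSpec keyword arguments
    features: list[str] = field(default_factory=lambda: ["bbenv"])
    bands: list[str] = field(default_factory=lambda: ["full"])
    references: list[str] = field(default_factory=lambda: ["avg_mastoid"])
    lag_tmin_ms: float = -100.0
    lag_tmax_ms: float = 1000.0
    lambda_grid: list[float] = field(default_factory=lambda: default_lambda_grid().tolist())
    n_perm: int = 0
    k_range: list[int] | None = None
    stimulus_name: str = "synthetic"
    output_dir: str = "envtrf_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    def cohort_spec(self) -> SyntheticCohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        return SyntheticCohortSpec(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    problems: list[str] = []
    for feat in config.features:
        if feat not in FEATURE_KINDS:
            problems.append(f"features: unknown feature kind {feat!r}")
    for band in config.bands:
        if band not in ("delta", "theta", "full"):
            problems.append(f"bands: unknown analysis band {band!r}")
    for ref in config.references:
        if ref not in ("avg_mastoid", "car"):
            problems.append(f"references: unknown reference scheme {ref!r}")
    if not config.lag_tmin_ms < config.lag_tmax_ms:
        problems.append("lag_tmin_ms: must be smaller than lag_tmax_ms")
    if not config.lambda_grid:
        problems.append("lambda_grid: must be non-empty")
    if config.n_perm < 0:
        problems.append("n_perm: must be >= 0")
    try:
        spec = config.cohort_spec()
    except (TypeError, ValueError) as err:
        problems.append(f"cohort: {err}")
        return problems
    if spec.n_tracks < 3:
        problems.append("cohort.n_tracks: leave-one-track-out CV needs at least 3 tracks")
    if config.k_range is not None:
        lo, hi = min(config.k_range), max(config.k_range)
        if lo < 3 or hi > spec.n_tracks:
            problems.append(f"k_range: must lie within 3..{spec.n_tracks}")
    return problems


def cohort_features(cohort: Cohort, kind: str) -> list[StimulusFeature]:
    """Stimulus features of one kind for every track of the cohort.

    Multiband kinds are z-scored per band over the concatenated track
    set, so cross-validation folds share one scale; broadband kinds are
    left unscaled.
    """
    fs = cohort.spec.fs_eeg
    if kind in ("bbenv", "bbenv_deriv"):
        feats = [compute_feature(s, kind, fs_out=fs) for s in cohort.stimuli]
    else:
        base = [compute_feature(s, "mbenv", fs_out=fs, zscore_mb=False) for s in cohort.stimuli]
        if kind == "mbenv_deriv":
            base = [temporal_derivative(f) for f in base]
        feats = zscore_feature_set(base)
    return feats


def preprocess_recording(
    rec: EEGRecording,
    reference: str = "avg_mastoid",
    band: str | None = "full",
    wideband: bool = True,
    bad_channels: bool = True,
    epoch_tmin_s: float = -5.0,
    epoch_tmax_s: float = 70.0,
) -> EEGRecording:
    """Standard conditioning chain for one recording.

    Resample to 128 Hz, 1-15 Hz wide-band filter, bad-channel
    replacement, artifact hook, epoching, average-mastoid reference (the
    common average, when requested, is computed from mastoid-referenced
    data), analysis-band filter, and pooled z-scoring.
    """
    if rec.fs > 128.0:
        rec = resample_eeg(rec, 128.0)
    if wideband:
        rec = bandpass_1_15(rec)
    if bad_channels:
        flagged = detect_bad_channels(rec)
        if flagged:
            rec = replace_channels(rec, flagged)
    rec = artifact_hook(rec)
    rec = epoch(rec, tmin_s=epoch_tmin_s, tmax_s=epoch_tmax_s)
    if rec.mastoid_channels is not None:
        rec = rereference(rec, "avg_mastoid")
    if reference == "car":
        rec = rereference(rec, "car")
    if band is not None:
        rec = band_filter(rec, band)
    return zscore_eeg(rec)


def build_trackset(
    rec: EEGRecording,
    features: list[StimulusFeature],
    lags: LagSpec,
    window_s: tuple[float, float] = (0.0, 65.0),
) -> TrackSet:
    """Per-track (design matrix, response) pairs for TRF estimation.

    Epochs are matched to features by track id; the analysis window is
    the 0-65 s post-onset segment (or the track duration if shorter).
    """
    by_id = {f.track_id: f for f in features}
    tracks = []
    for onset, tid in rec.epochs:
        feat = by_id[tid]
        n = min(feat.n_samples, int(round((window_s[1] - window_s[0]) * rec.fs)))
        X = lag_matrix(feat, lags)[:n]
        Y = epoch_window(rec, onset, window_s[0], window_s[1])[:, :n].T
        tracks.append((X, Y[: X.shape[0]]))
    return TrackSet(tracks)


def cohort_tracksets(
    cohort: Cohort,
    feature_kind: str = "bbenv",
    lags: LagSpec | None = None,
    zscore: bool = True,
    features: list[StimulusFeature] | None = None,
) -> dict[tuple[int, int], TrackSet]:
    """Per-recording TrackSets on the direct path (no filtering stages).

    All recordings share the same stimuli, so the design matrices and
    their Gram matrices are built once and reused; only the EEG responses
    differ.  Used for ground-truth recovery and cohort-level reliability
    analyses where the filtering stages are not under study.
    """
    spec = cohort.spec
    lags = lags or LagSpec(fs=spec.fs_eeg)
    if features is None:
        features = cohort_features(cohort, feature_kind)
    first = next(iter(sorted(cohort.recordings)))
    window = (0.0, min(65.0, spec.track_duration_s))
    base = build_trackset(cohort.recordings[first], features, lags, window_s=window)
    out = {}
    for key, rec in sorted(cohort.recordings.items()):
        r = zscore_eeg(rec) if zscore else rec
        ys = []
        for (onset, _), X in zip(r.epochs, base.X):
            Y = epoch_window(r, onset, window[0], window[1]).T
            ys.append(Y[: X.shape[0]])
        out[key] = base.with_responses(ys)
    return out


def cohort_accuracy_table(
    cohort: Cohort,
    feature_kind: str = "bbenv",
    lam: float = 100.0,
    channel: int | None = None,
    k: int | None = None,
) -> np.ndarray:
    """(n_subjects x 2) table of cross-validated prediction accuracies.

    Direct estimation path with a fixed ridge parameter.  ``channel``
    selects one channel's fold-mean accuracy; None averages over all
    channels.  ``k`` restricts estimation to the first k tracks.
    """
    tsets = cohort_tracksets(cohort, feature_kind)
    table = np.empty((cohort.spec.n_subjects, 2))
    for (i, s), ts in tsets.items():
        if k is not None:
            ts = ts.subset(k)
        mean_r = cross_validate(ts, lam).mean_r
        table[i, s - 1] = mean_r.mean() if channel is None else mean_r[channel]
    return table


def run_condition(
    cohort: Cohort,
    feature_kind: str,
    band: str,
    reference: str,
    lags: LagSpec | None = None,
    grid=None,
    n_perm: int = 0,
    k_range=None,
    seed: int = 0,
    features: list[StimulusFeature] | None = None,
) -> dict:
    """Fit and evaluate one (feature, band, reference) condition.

    Returns per-subject/session accuracies, ridge parameters and TRFs,
    plus condition-level reliability tables.
    """
    spec = cohort.spec
    lags = lags or LagSpec(fs=spec.fs_eeg)
    if features is None:
        features = cohort_features(cohort, feature_kind)
    accs: dict[tuple[int, int], object] = {}
    lams: dict[tuple[int, int], float] = {}
    trfs: dict[tuple[int, int], TRFModel] = {}
    chance: dict[tuple[int, int], np.ndarray] = {}
    tracksets: dict[tuple[int, int], TrackSet] = {}
    # epoch window capped by the track layout (-5..70 s for >= 65 s tracks)
    tmax = min(70.0, spec.track_duration_s + 5.0)
    for (i, s), rec in sorted(cohort.recordings.items()):
        pre = preprocess_recording(rec, reference=reference, band=band, epoch_tmax_s=tmax)
        window = (0.0, min(65.0, spec.track_duration_s))
        ts = build_trackset(pre, features, lags, window_s=window)
        lam = select_lambda(ts, grid)
        acc = cross_validate(ts, lam)
        if n_perm > 0:
            perm_seed = np.random.SeedSequence(seed, spawn_key=(900, i, s))
            acc.chance_samples = permutation_null(ts, lam, n_perm=n_perm, seed=perm_seed)
            chance[(i, s)] = acc.chance_samples
        w = ts.fit_all(lam)
        n_bands = (ts.X[0].shape[1] - 1) // lags.n_lags
        coef = w[:-1].reshape(n_bands, lags.n_lags, -1).transpose(1, 0, 2)
        trfs[(i, s)] = TRFModel(
            weights=coef, bias=w[-1], lam=lam, lag_axis_ms=lags.lag_axis_ms,
            feature_kind=feature_kind, band=band, reference=reference,
        )
        accs[(i, s)] = acc
        lams[(i, s)] = lam
        tracksets[(i, s)] = ts

    n_channels = next(iter(cohort.recordings.values())).n_channels
    cz = cohort.ground_truth.cz_index if cohort.ground_truth is not None else n_channels // 2
    subjects = sorted({i for i, _ in accs})
    acc_table = np.stack(
        [np.column_stack([accs[(i, 1)].mean_r, accs[(i, 2)].mean_r]) for i in subjects]
    )  # subjects x channels x 2

    icc_channels = []
    for ch in range(n_channels):
        try:
            icc_channels.append(icc_a1(acc_table[:, ch, :]))
        except ValueError:
            icc_channels.append(None)
    tc = icc_timecourse(
        [trfs[(i, 1)] for i in subjects], [trfs[(i, 2)] for i in subjects], channel=cz
    ) if len(subjects) >= 3 else []
    ba = bland_altman(acc_table[:, cz, :]) if len(subjects) >= 2 else None

    amount = None
    if k_range is not None:
        per_subject = []
        for i in subjects:
            per_subject.append(
                accuracy_vs_data_amount(
                    {1: tracksets[(i, 1)], 2: tracksets[(i, 2)]}, grid=grid, k_range=k_range
                )
            )
        per_k = []
        for j, (k, _) in enumerate(per_subject[0]):
            table = np.array(
                [
                    [per_subject[m][j][1][1].mean_r[cz], per_subject[m][j][1][2].mean_r[cz]]
                    for m in range(len(subjects))
                ]
            )
            per_k.append((k, table))
        amount = icc_by_data_amount(per_k, channel=cz)

    return {
        "feature": feature_kind,
        "band": band,
        "reference": reference,
        "subjects": subjects,
        "cz": cz,
        "accuracies": accs,
        "lambdas": lams,
        "trfs": trfs,
        "chance": chance,
        "acc_table": acc_table,
        "icc_channels": icc_channels,
        "icc_timecourse": tc,
        "bland_altman": ba,
        "icc_by_amount": amount,
    }


def _write_condition(outdir: Path, res: dict, stimulus: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    feature, band, reference = res["feature"], res["band"], res["reference"]
    ctx = {"stimulus": stimulus, "feature": feature, "band": band, "reference": reference}

    rows = []
    for (i, s), acc in sorted(res["accuracies"].items()):
        for fold in range(acc.n_folds):
            for ch, r in enumerate(acc.r_per_fold[fold]):
                rows.append({**ctx, "subject": i, "session": s, "channel": ch, "fold": fold, "r": r})
    pd.DataFrame(rows).to_csv(outdir / "accuracy.csv", index=False, float_format=_CSV_FLOAT)

    rows = []
    for ch, icc in enumerate(res["icc_channels"]):
        if icc is None:
            continue
        rows.append(
            {**ctx, "channel": ch, "icc": icc.icc, "ci_lo": icc.ci95[0], "ci_hi": icc.ci95[1],
             "p": icc.p, "label": icc.label}
        )
    pd.DataFrame(rows).to_csv(outdir / "icc_accuracy.csv", index=False, float_format=_CSV_FLOAT)

    rows = [
        {**ctx, "lag_ms": lag, "icc": r.icc, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "p": r.p,
         "label": r.label}
        for lag, r in res["icc_timecourse"]
    ]
    pd.DataFrame(rows).to_csv(outdir / "icc_trf_timecourse.csv", index=False, float_format=_CSV_FLOAT)

    ba = res["bland_altman"]
    if ba is not None:
        pd.DataFrame(
            {**ctx, "subject": res["subjects"], "mean": ba.means, "diff": ba.diffs}
        ).to_csv(outdir / "bland_altman.csv", index=False, float_format=_CSV_FLOAT)
        (outdir / "bland_altman.json").write_text(
            json.dumps(
                {"mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                 "loa_lo": ba.loa[0], "loa_hi": ba.loa[1], "n": ba.n},
                indent=1,
            )
        )

    if res["icc_by_amount"] is not None:
        rows = [
            {**ctx, "k": k, "icc": r.icc, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "p": r.p,
             "label": r.label}
            for k, r in res["icc_by_amount"]
        ]
        pd.DataFrame(rows).to_csv(outdir / "icc_by_data_amount.csv", index=False, float_format=_CSV_FLOAT)

    if res["chance"]:
        rows = []
        for (i, s), samples in sorted(res["chance"].items()):
            for ch, cm in enumerate(samples.mean(axis=0)):
                rows.append({**ctx, "subject": i, "session": s, "channel": ch, "chance_mean_r": cm})
        pd.DataFrame(rows).to_csv(outdir / "chance.csv", index=False, float_format=_CSV_FLOAT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every condition of the config and write results under output_dir.

    Returns a manifest dict (also written as ``manifest.json``).  A
    failing condition is recorded and the remaining conditions still run;
    the manifest's ``failures`` list is non-empty in that case.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(config.cohort_spec())
    lags = LagSpec(config.lag_tmin_ms, config.lag_tmax_ms, fs=cohort.spec.fs_eeg)
    feature_cache = {kind: cohort_features(cohort, kind) for kind in set(config.features)}

    conditions, failures = [], []
    for feature in config.features:
        for band in config.bands:
            for reference in config.references:
                name = f"{feature}/{band}/{reference}"
                try:
                    res = run_condition(
                        cohort, feature, band, reference,
                        lags=lags, grid=config.lambda_grid, n_perm=config.n_perm,
                        k_range=config.k_range, seed=config.seed,
                        features=feature_cache[feature],
                    )
                    _write_condition(outdir / feature / band / reference, res, config.stimulus_name)
                    conditions.append(name)
                except Exception as err:  # noqa: BLE001 - keep remaining conditions running
                    logger.exception("condition %s failed", name)
                    failures.append({"condition": name, "error": str(err)})
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "conditions": conditions,
        "failures": failures,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
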