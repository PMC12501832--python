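"""Forward TRF estimation by ridge regression over lagged stimulus features.

The temporal response function (TRF) ``w(lag, band, channel)`` maps
time-lagged stimulus features to the multichannel EEG response:

    y_c[t] = sum_{b, l} w[l, b, c] * s_b[t - l] + bias_c

Weights are estimated by ridge regression, ``w = (X'X + lam*M)^-1 X'Y``
with ``M`` the identity over lag columns and 0 for the bias column.  The
ridge parameter is selected per participant by leave-one-track-out
cross-validation; prediction accuracy is the per-channel Pearson
correlation between observed and predicted EEG on held-out tracks, and a
chance level is obtained by re-pairing stimuli and EEG tracks with random
derangements.

Per-track Gram matrices (``X'X``, ``X'Y``) are cached so that
cross-validation folds, the ridge-parameter grid search and the
permutation null all reuse the same accumulations.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .containers import EEGRecording, LagSpec, PredictionAccuracy, StimulusFeature, TRFModel

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_eeg",
    "lag_matrix",
    "ridge_fit",
    "default_lambda_grid",
    "select_lambda",
    "cross_validate",
    "permutation_null",
    "accuracy_vs_data_amount",
    "TrackSet",
]

#: Conventional ridge-parameter grid: 9 log-spaced values, 1e-2..1e6.
def default_lambda_grid() -> np.ndarray:
    return np.logspace(-2, 6, 9)


def zscore_eeg(rec: EEGRecording) -> EEGRecording:
    """Standardise every channel with the grand mean/SD pooled over channels.

    A single affine map is applied to all channels, so between-channel
    amplitude ratios are preserved; the pooled mean becomes 0 and the
    pooled SD becomes 1.
    """
    mu = rec.data.mean()
    sd = rec.data.std()
    if sd == 0:
        raise ValueError("zero pooled SD; cannot z-score EEG")
    return rec.copy_with(data=(rec.data - mu) / sd)


def lag_matrix(feature: StimulusFeature, lags: LagSpec) -> np.ndarray:
    """Lagged design matrix, shape (n_samples, n_lags * n_bands + 1).

    Column ``(b, l)`` holds band ``b`` delayed by lag ``l`` samples
    (positive lag = stimulus leads the response): ``X[t, (b,l)] =
    s_b[t-l]`` with zero padding outside the track.  Columns are ordered
    band-major (all lags of band 0, then band 1, ...) and a constant
    column for the bias is appended last.
    """
    if feature.fs != lags.fs:
        raise ValueError("feature rate must match the lag specification rate")
    n, n_bands = feature.values.shape
    lag_vals = lags.lags
    if n <= max(abs(lags.lag_min), abs(lags.lag_max)):
        raise ValueError("feature is shorter than the maximum lag")
    X = np.zeros((n, lags.n_lags * n_bands + 1))
    for b in range(n_bands):
        s = feature.values[:, b]
        for j, l in enumerate(lag_vals):
            col = b * lags.n_lags + j
            if l >= 0:
                X[l:, col] = s[: n - l]
            else:
                X[: n + l, col] = s[-l:]
    X[:, -1] = 1.0
    return X


def _penalty_diag(n_cols: int) -> np.ndarray:
    m = np.ones(n_cols)
    m[-1] = 0.0  # bias column unpenalised
    return m


def _solve_ridge(xtx: np.ndarray, xty: np.ndarray, lam: float) -> np.ndarray:
    A = xtx + lam * np.diag(_penalty_diag(xtx.shape[0]))
    try:
        return linalg.solve(A, xty, assume_a="pos")
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"ridge system singular at lambda={lam!r}; raise the ridge parameter"
        ) from err


def _reshape_weights(
    w: np.ndarray, lags: LagSpec, n_bands: int, lam: float, feature_kind: str = "bbenv"
) -> TRFModel:
    coef = w[:-1].reshape(n_bands, lags.n_lags, -1).transpose(1, 0, 2)
    return TRFModel(
        weights=coef,
        bias=w[-1],
        lam=lam,
        lag_axis_ms=lags.lag_axis_ms,
        feature_kind=feature_kind,
    )


def ridge_fit(X: np.ndarray, Y: np.ndarray, lam: float, lags: LagSpec | None = None) -> TRFModel:
    """Ridge solution ``(X'X + lam*M)^-1 X'Y`` reshaped to lags x bands x channels.

    ``lags`` is needed to reshape the flat coefficient vector; if omitted a
    single band covering all non-bias columns is assumed.
    """
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    if lam < 0:
        raise ValueError("ridge parameter must be >= 0")
    Y = np.atleast_2d(Y.T).T
    w = _solve_ridge(X.T @ X, X.T @ Y, lam)
    if lags is None:
        lags = LagSpec(tmin_ms=0.0, tmax_ms=(X.shape[1] - 2) * 1000.0, fs=1000.0)
    n_bands = (X.shape[1] - 1) // lags.n_lags
    return _reshape_weights(w, lags, n_bands, lam)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (samples x channels) arrays.

    Zero-variance columns yield NaN (handled by the caller).
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return r


class TrackSet:
    """Per-track design matrices and responses with cached Gram matrices.

    ``tracks`` is a list of ``(X, Y)`` pairs: X (samples x p) includes the
    bias column, Y is (samples x channels).  Cross-products for mismatched
    stimulus/EEG pairings are cached lazily for the permutation null.
    """

    def __init__(self, tracks: list[tuple[np.ndarray, np.ndarray]]):
        if not tracks:
            raise ValueError("empty track list")
        p = tracks[0][0].shape[1]
        c = tracks[0][1].shape[1]
        for X, Y in tracks:
            if X.shape[0] != Y.shape[0] or X.shape[1] != p or Y.shape[1] != c:
                raise ValueError("inconsistent track shapes")
        self.X = [X for X, _ in tracks]
        self.Y = [Y for _, Y in tracks]
        self.n_tracks = len(tracks)
        self.n_channels = c
        self.xtx = [X.T @ X for X in self.X]
        self._xty: dict[tuple[int, int], np.ndarray] = {}

    def xty(self, i: int, j: int) -> np.ndarray:
        """Cross-product of design matrix i with response j."""
        key = (i, j)
        if key not in self._xty:
            self._xty[key] = self.X[i].T @ self.Y[j]
        return self._xty[key]

    def cv_mean_r(self, lam: float, pairing: list[int] | None = None) -> np.ndarray:
        """Leave-one-track-out CV accuracies, (n_folds x channels).

        ``pairing[t]`` gives the stimulus (design) track paired with EEG
        track ``t``; None means the matched pairing.
        """
        if pairing is None:
            pairing = list(range(self.n_tracks))
        sum_xtx = sum(self.xtx[p] for p in pairing)
        sum_xty = sum(self.xty(p, t) for t, p in enumerate(pairing))
        r = np.empty((self.n_tracks, self.n_channels))
        for k in range(self.n_tracks):
            pk = pairing[k]
            w = _solve_ridge(sum_xtx - self.xtx[pk], sum_xty - self.xty(pk, k), lam)
            pred = self.X[pk] @ w
            rk = _pearson_columns(pred, self.Y[k])
            if np.any(np.isnan(rk)):
                logger.warning("fold %d: zero-variance channel(s); r recorded as missing", k)
            r[k] = rk
        return r

    def fit_all(self, lam: float) -> np.ndarray:
        """Ridge weights (flat, incl. bias row) fitted on all tracks."""
        sum_xtx = sum(self.xtx)
        sum_xty = sum(self.xty(t, t) for t in range(self.n_tracks))
        return _solve_ridge(sum_xtx, sum_xty, lam)

    def with_responses(self, responses: list[np.ndarray]) -> "TrackSet":
        """New TrackSet with the same designs (and cached X'X) but new EEG.

        Useful when every subject heard the same stimuli: the design-side
        Gram matrices are computed once and shared.
        """
        if len(responses) != self.n_tracks:
            raise ValueError("response count must match track count")
        out = TrackSet.__new__(TrackSet)
        out.X = self.X
        out.Y = [np.asarray(y) for y in responses]
        out.n_tracks = self.n_tracks
        out.n_channels = out.Y[0].shape[1]
        out.xtx = self.xtx
        out._xty = {}
        return out

    def subset(self, k: int) -> "TrackSet":
        """First-k-tracks subset, sharing the cached Gram matrices."""
        sub = TrackSet.__new__(TrackSet)
        sub.X = self.X[:k]
        sub.Y = self.Y[:k]
        sub.n_tracks = k
        sub.n_channels = self.n_channels
        sub.xtx = self.xtx[:k]
        sub._xty = self._xty  # shared cache; keys restricted by use
        return sub


def _as_trackset(tracks) -> TrackSet:
    return tracks if isinstance(tracks, TrackSet) else TrackSet(list(tracks))


def select_lambda(tracks, grid=None) -> float:
    """Ridge parameter maximising mean CV accuracy over channels and folds.

    Ties (within 1e-12) are broken toward the larger ridge parameter.
    """
    ts = _as_trackset(tracks)
    if ts.n_tracks < 3:
        raise ValueError("ridge-parameter selection needs at least 3 tracks")
    grid = np.sort(np.asarray(default_lambda_grid() if grid is None else grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty ridge-parameter grid")
    best_lam, best_score = None, -np.inf
    for lam in grid:  # ascending, so >= ties resolve toward the larger value
        score = np.nanmean(ts.cv_mean_r(lam))
        if np.isnan(score):
            continue
        if score >= best_score - 1e-12:
            best_lam, best_score = float(lam), max(score, best_score)
    if best_lam is None:
        raise ValueError("all cross-validated accuracies were undefined")
    return best_lam


def cross_validate(tracks, lam: float) -> PredictionAccuracy:
    """Leave-one-track-out CV: per-fold, per-channel Pearson accuracies."""
    ts = _as_trackset(tracks)
    return PredictionAccuracy(r_per_fold=ts.cv_mean_r(lam))


def _derangement(rng: np.random.Generator, n: int) -> list[int]:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm.tolist()


def permutation_null(tracks, lam: float, n_perm: int = 100, seed=0) -> np.ndarray:
    """Chance-level accuracies from mismatched stimulus/EEG pairings.

    Each permutation re-pairs stimulus tracks with EEG tracks by a random
    derangement (no track keeps its own stimulus), runs the full
    leave-one-track-out CV, and records the fold-mean r per channel.
    Returns an (n_perm x channels) array.
    """
    ts = _as_trackset(tracks)
    if ts.n_tracks < 2:
        raise ValueError("permutation null needs at least 2 tracks (no derangement exists)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, ts.n_channels))
    for p in range(n_perm):
        pairing = _derangement(rng, ts.n_tracks)
        out[p] = np.nanmean(ts.cv_mean_r(lam, pairing=pairing), axis=0)
    return out


def accuracy_vs_data_amount(
    tracks_by_session: dict[int, "TrackSet | list"],
    grid=None,
    k_range=None,
    lam: float | None = None,
) -> list[tuple[int, dict[int, PredictionAccuracy]]]:
    """Re-run estimation on the first k tracks per session, k in ``k_range``.

    For each k the ridge parameter is re-selected (unless ``lam`` is
    given) and leave-one-track-out CV is run on the first k tracks of each
    session; the same k applies to both sessions.  Returns
    ``[(k, {session: PredictionAccuracy}), ...]`` ready for the
    ICC-by-data-amount analysis.
    """
    sets = {s: _as_trackset(t) for s, t in tracks_by_session.items()}
    n_tracks = min(ts.n_tracks for ts in sets.values())
    if k_range is None:
        k_range = range(3, n_tracks + 1)
    out = []
    for k in k_range:
        if not 3 <= k <= n_tracks:
            raise ValueError(f"k={k} outside the valid range 3..{n_tracks}")
        per_session = {}
        for s, ts in sets.items():
            sub = ts.subset(k)
            lam_k = select_lambda(sub, grid) if lam is None else lam
            per_session[s] = cross_validate(sub, lam_k)
        out.append((int(k), per_session))
    return out
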