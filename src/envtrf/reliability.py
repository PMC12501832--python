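"""Test-retest agreement statistics for two-session designs.

The central quantity is the intraclass correlation ICC(A,1) of McGraw &
Wong: two-way model, absolute agreement, single measurement.  With ``n``
subjects measured in ``k = 2`` sessions, the two-way ANOVA mean squares
(rows = subjects, columns = sessions) give

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with the F-based 95% confidence interval and a one-sided p-value for
H0: ICC = 0 from F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
Point estimates are reported as computed (negative values are possible
and are labelled "poor").

Also provided: the conventional interpretation bins (poor < 0.50 <=
moderate < 0.75 <= good <= 0.90 < excellent), Bland-Altman agreement
summaries (mean difference and +/-1.96 SD limits), ICC as a function of
the amount of data, an RMS-ratio SNR, a 10*log10(RMS) intensity measure,
and Benjamini-Hochberg FDR thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .containers import AudioStimulus, EEGRecording, PredictionAccuracy, TRFModel
from .preprocess import concat_epoch_windows

__all__ = [
    "ICCResult",
    "BlandAltman",
    "icc_a1",
    "classify_icc",
    "icc_timecourse",
    "bland_altman",
    "icc_by_data_amount",
    "snr",
    "rms_log",
    "fdr_bh",
]


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    n: int
    k: int = 2

    @property
    def label(self) -> str:
        return classify_icc(self.icc)


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    n: int
    means: np.ndarray  # per-subject mean of the two sessions (x-axis)
    diffs: np.ndarray  # per-subject session-1 minus session-2 (y-axis)

    @property
    def loa(self) -> tuple[float, float]:
        """Limits of agreement: mean difference +/- 1.96 SD."""
        return (self.mean_diff - 1.96 * self.sd_diff, self.mean_diff + 1.96 * self.sd_diff)


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x sessions) ANOVA mean squares (MSR, MSC, MSE)."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((table - grand) ** 2)
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_a1(table: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    ``table`` is (n_subjects, k_sessions); n >= 3 and k = 2 for the
    two-session design (any k >= 2 is accepted).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (subjects x sessions)")
    n, k = table.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 sessions")
    if np.any(~np.isfinite(table)):
        raise ValueError("table contains missing values; apply listwise deletion upstream")
    if np.ptp(table) == 0:
        raise ValueError("zero total variance: ICC undefined for a constant table")
    msr, msc, mse = _anova_mean_squares(table)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("degenerate variance structure: ICC undefined")
    icc = (msr - mse) / denom

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        p = 0.0
    else:
        p = float(f_dist.sf(msr / mse, df1, df2))

    # F-based CI (McGraw & Wong case A,1) via the Satterthwaite df 'v'
    if mse > 0:
        fj = msc / mse
        a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        vn = df2 * a**2
        vd = df1 * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = f_dist.ppf(1 - alpha / 2, df1, v)
        f_l = f_dist.ppf(1 - alpha / 2, v, df1)
        lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        lo = hi = 1.0
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ICCResult(icc=float(icc), ci95=(lo, hi), p=p, n=n, k=k)


def classify_icc(icc: float) -> str:
    """Interpretation bins; boundary values take the higher category."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc > 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def icc_timecourse(
    trfs_s1: list[TRFModel],
    trfs_s2: list[TRFModel],
    channel: int,
    band: int = 0,
    window_ms: tuple[float, float] = (-50.0, 950.0),
) -> list[tuple[float, ICCResult]]:
    """Per-lag ICC(A,1) of TRF weights across subjects, within ``window_ms``.

    For each lag in the window the subjects x 2 table of TRF weights at
    ``channel`` (and feature band ``band``) is assembled and ICC(A,1)
    computed; returns ``[(lag_ms, ICCResult), ...]``.
    """
    if len(trfs_s1) != len(trfs_s2) or len(trfs_s1) < 3:
        raise ValueError("need matched session lists with at least 3 subjects")
    axis = trfs_s1[0].lag_axis_ms
    for m in trfs_s1 + trfs_s2:
        if not np.array_equal(m.lag_axis_ms, axis):
            raise ValueError("TRFs must share a common lag axis")
    # window edges follow the lag-rounding rule: convert to integer lag
    # samples (round half away from the origin symmetric rounding), so
    # -50..950 ms at 128 Hz selects lags -6..122 (129 points)
    step = float(np.median(np.diff(axis)))
    lag_int = np.round(axis / step).astype(int)
    lo = int(round(window_ms[0] / step))
    hi = int(round(window_ms[1] / step))
    mask = (lag_int >= lo) & (lag_int <= hi)
    if not mask.any():
        raise ValueError("window lies outside the TRF lag axis")
    w1 = np.stack([m.weights[mask, band, channel] for m in trfs_s1])  # subjects x lags
    w2 = np.stack([m.weights[mask, band, channel] for m in trfs_s2])
    out = []
    for j, lag_ms in enumerate(axis[mask]):
        out.append((float(lag_ms), icc_a1(np.column_stack([w1[:, j], w2[:, j]]))))
    return out


def bland_altman(table: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement: session-1 minus session-2 differences."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("table must be (n >= 2) x 2")
    diffs = table[:, 0] - table[:, 1]
    means = table.mean(axis=1)
    return BlandAltman(
        mean_diff=float(diffs.mean()),
        sd_diff=float(diffs.std(ddof=1)),
        n=table.shape[0],
        means=means,
        diffs=diffs,
    )


def icc_by_data_amount(
    per_k: list[tuple[int, dict[int, "PredictionAccuracy"]]],
    channel: int,
) -> list[tuple[int, ICCResult]]:
    """ICC(A,1) of per-subject accuracies at one channel for each data amount.

    ``per_k`` maps each k to ``{session: list/array of per-subject
    PredictionAccuracy}``; entries may also be pre-assembled (n x 2)
    tables, in which case ``channel`` is ignored.
    """
    out = []
    for k, sessions in per_k:
        if isinstance(sessions, np.ndarray):
            table = sessions
        else:
            s_ids = sorted(sessions)
            cols = []
            for s in s_ids:
                accs = sessions[s]
                cols.append([a.mean_r[channel] for a in accs])
            table = np.column_stack(cols)
        out.append((int(k), icc_a1(table)))
    return out


def snr(rec: EEGRecording, pre_s: float = 5.0, post_s: float = 65.0) -> np.ndarray:
    """Per-channel RMS(post-stimulus) / RMS(pre-stimulus) over all epochs."""
    if not rec.epochs:
        raise ValueError("recording has no epochs")
    pre = concat_epoch_windows(rec, -pre_s, 0.0)
    post = concat_epoch_windows(rec, 0.0, post_s)
    rms_pre = np.sqrt(np.mean(pre**2, axis=1))
    rms_post = np.sqrt(np.mean(post**2, axis=1))
    if np.any(rms_pre == 0):
        raise ValueError("zero pre-stimulus RMS; SNR undefined")
    return rms_post / rms_pre


def rms_log(audio: AudioStimulus) -> float:
    """Intensity measure: 10 * log10(RMS of the waveform)."""
    rms = np.sqrt(np.mean(np.asarray(audio.samples, dtype=float) ** 2))
    if rms == 0:
        raise ValueError("all-zero audio: intensity undefined")
    return float(10.0 * np.log10(rms))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of discoveries at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject
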