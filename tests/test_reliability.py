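"""Reliability statistics: ICC(A,1), Bland-Altman, SNR, intensity, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envtrf.containers import AudioStimulus, EEGRecording, TRFModel
from envtrf.reliability import (
    bland_altman,
    classify_icc,
    fdr_bh,
    icc_a1,
    icc_by_data_amount,
    icc_timecourse,
    rms_log,
    snr,
)


def icc_a1_brute(table):
    """Loop-written two-way ANOVA variance-components oracle for ICC(A,1)."""
    n, k = table.shape
    grand = sum(table[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = ssc = sst = 0.0
    for i in range(n):
        row_mean = sum(table[i, j] for j in range(k)) / k
        ssr += k * (row_mean - grand) ** 2
    for j in range(k):
        col_mean = sum(table[i, j] for i in range(n)) / n
        ssc += n * (col_mean - grand) ** 2
    for i in range(n):
        for j in range(k):
            sst += (table[i, j] - grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestIccA1:
    @pytest.mark.parametrize("n,seed", [(6, 0), (6, 1), (30, 2), (30, 3)])
    def test_matches_brute_force_anova_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        table = rng.standard_normal((n, 1)) + 0.5 * rng.standard_normal((n, 2))
        res = icc_a1(table)
        assert res.icc == pytest.approx(icc_a1_brute(table), abs=1e-10)

    def test_duplicated_sessions_give_one(self):
        col = np.array([0.1, 0.4, 0.2, 0.9, 0.3, 0.6])
        res = icc_a1(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.p < 1e-20

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        table = rng.standard_normal((2000, 2))
        assert abs(icc_a1(table).icc) < 0.08

    def test_matches_pingouin_reference(self):
        # independent reference implementation of ICC(A,1) ("ICC2")
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        table = rng.standard_normal((12, 1)) + 0.7 * rng.standard_normal((12, 2))
        res = icc_a1(table)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile([1, 2], 12),
                "ratings": table.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.p == pytest.approx(row["pval"], abs=1e-9)
        np.testing.assert_allclose(res.ci95, row["CI95"], atol=0.005)  # pingouin rounds its CI

    def test_constant_table_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            icc_a1(np.full((6, 2), 1.5))

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(np.ones((2, 2)) + np.eye(2))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            table = rng.standard_normal((8, 1)) + rng.standard_normal((8, 2))
            res = icc_a1(table)
            assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_null_pvalue_calibration(self):
        # under zero between-subject variance the test should reject at
        # most ~5% of the time (<= 7% over 400 null tables)
        rng = np.random.default_rng(7)
        rejections = sum(icc_a1(rng.standard_normal((10, 2))).p < 0.05 for _ in range(400))
        assert rejections <= 0.07 * 400


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    shift=st.floats(min_value=-10, max_value=10),
    scale=st.floats(min_value=0.1, max_value=10),
    seed=st.integers(min_value=0, max_value=100),
)
def test_icc_affine_invariance(shift, scale, seed):
    """Applying one affine map to both sessions leaves ICC(A,1) unchanged."""
    rng = np.random.default_rng(seed)
    table = rng.standard_normal((9, 1)) + 0.5 * rng.standard_normal((9, 2))
    a = icc_a1(table).icc
    b = icc_a1(scale * table + shift).icc
    assert a == pytest.approx(b, abs=1e-9)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.92, "excellent"),
            (0.60, "moderate"),
            (0.75, "good"),   # boundary assigned upward
            (0.90, "good"),
            (0.50, "moderate"),
            (0.49, "poor"),
            (-0.2, "poor"),   # negative estimates reported as computed
        ],
    )
    def test_bins(self, value, label):
        assert classify_icc(value) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(float("nan"))


def _trf(weights_1d, lag_axis_ms):
    w = np.asarray(weights_1d)[:, None, None]
    return TRFModel(weights=w, bias=np.zeros(1), lam=1.0, lag_axis_ms=np.asarray(lag_axis_ms))


class TestIccTimecourse:
    def test_identical_sessions_give_one_everywhere(self):
        rng = np.random.default_rng(8)
        axis = np.arange(-13, 129) * 1000.0 / 128.0
        trfs = [_trf(rng.standard_normal(axis.size), axis) for _ in range(5)]
        out = icc_timecourse(trfs, [_trf(m.weights[:, 0, 0], axis) for m in trfs], channel=0)
        assert all(res.icc == pytest.approx(1.0, abs=1e-9) for _, res in out)

    def test_window_lag_count(self):
        axis = np.arange(-13, 129) * 1000.0 / 128.0
        rng = np.random.default_rng(9)
        trfs1 = [_trf(rng.standard_normal(axis.size), axis) for _ in range(4)]
        trfs2 = [_trf(rng.standard_normal(axis.size), axis) for _ in range(4)]
        out = icc_timecourse(trfs1, trfs2, channel=0, window_ms=(-50.0, 950.0))
        # lags -6..122 at 128 Hz: -46.9..953 ms window contains 129 points
        assert len(out) == 129

    def test_noise_matched_to_subject_variance_gives_mid_icc(self):
        # session 2 = session 1 + noise with SD equal to the between-subject
        # SD: variance-ratio oracle predicts ICC about 0.5
        axis = np.arange(0, 64) * 1000.0 / 128.0
        medians = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            base = rng.standard_normal(axis.size)
            subj = [base + rng.standard_normal(axis.size) for _ in range(30)]
            t1 = [_trf(s, axis) for s in subj]
            t2 = [_trf(s + rng.standard_normal(axis.size), axis) for s in subj]
            out = icc_timecourse(t1, t2, channel=0, window_ms=(0.0, 500.0))
            medians.append(np.median([r.icc for _, r in out]))
        assert 0.3 < np.median(medians) < 0.7

    def test_window_outside_axis_rejected(self):
        axis = np.arange(0, 64) * 1000.0 / 128.0
        rng = np.random.default_rng(10)
        trfs = [_trf(rng.standard_normal(axis.size), axis) for _ in range(3)]
        with pytest.raises(ValueError, match="window"):
            icc_timecourse(trfs, trfs, channel=0, window_ms=(2000.0, 3000.0))


class TestBlandAltman:
    def test_identical_sessions(self):
        col = np.array([0.2, 0.5, 0.7])
        res = bland_altman(np.column_stack([col, col]))
        assert res.mean_diff == 0.0
        assert res.loa == (0.0, 0.0)

    def test_constant_offset(self):
        col = np.array([0.2, 0.5, 0.7])
        res = bland_altman(np.column_stack([col + 0.5, col]))
        assert res.mean_diff == pytest.approx(0.5, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_limits(self):
        # diffs {-1, +1}: mean 0, sample SD sqrt(2), limits +/-1.96*sqrt(2)
        table = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = bland_altman(table)
        assert res.mean_diff == pytest.approx(0.0, abs=1e-12)
        lo, hi = res.loa
        assert hi == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-9)
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-9)

    def test_limits_contain_most_gaussian_points(self):
        rng = np.random.default_rng(11)
        table = np.column_stack([rng.standard_normal(200), rng.standard_normal(200)])
        res = bland_altman(table)
        lo, hi = res.loa
        frac = np.mean((res.diffs >= lo) & (res.diffs <= hi))
        assert frac >= 0.93


class TestIccByDataAmount:
    def test_counting_and_prebuilt_tables(self):
        rng = np.random.default_rng(12)
        per_k = [
            (k, rng.standard_normal((8, 1)) + 0.5 * rng.standard_normal((8, 2)))
            for k in range(3, 13)
        ]
        out = icc_by_data_amount(per_k, channel=0)
        assert [k for k, _ in out] == list(range(3, 13))
        assert all(-1 <= r.icc <= 1 for _, r in out)


class TestSnrAndIntensity:
    def _rec_with_epochs(self, rng, post_scale=1.0):
        fs = 128.0
        n_pre, n_post = int(5 * fs), int(10 * fs)
        blocks, onsets, pos = [], [], 0
        for _ in range(3):
            pre = rng.standard_normal((4, n_pre))
            post = post_scale * rng.standard_normal((4, n_post))
            blocks += [pre, post]
            onsets.append(pos + n_pre)
            pos += n_pre + n_post
        data = np.concatenate(blocks, axis=1)
        return EEGRecording(data=data, fs=fs, epochs=[(o, f"t{i}") for i, o in enumerate(onsets)])

    def test_stationary_noise_gives_ratio_one(self):
        ratios = []
        for seed in range(10):
            rec = self._rec_with_epochs(np.random.default_rng(seed))
            ratios.append(snr(rec, pre_s=5.0, post_s=10.0).mean())
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_doubled_post_amplitude_doubles_ratio(self):
        rec = self._rec_with_epochs(np.random.default_rng(13), post_scale=2.0)
        ratios = snr(rec, pre_s=5.0, post_s=10.0)
        np.testing.assert_allclose(ratios, 2.0, rtol=0.1)

    def test_zero_post_signal_gives_zero(self):
        rec = self._rec_with_epochs(np.random.default_rng(14), post_scale=0.0)
        assert np.all(snr(rec, pre_s=5.0, post_s=10.0) == 0.0)

    def test_rms_log_values(self):
        assert rms_log(AudioStimulus(samples=np.ones(100), fs=1000.0)) == pytest.approx(0.0)
        assert rms_log(AudioStimulus(samples=10 * np.ones(100), fs=1000.0)) == pytest.approx(10.0)
        t = np.arange(100000) / 1000.0
        sine = AudioStimulus(samples=np.sin(2 * np.pi * 5.0 * t), fs=1000.0)
        assert rms_log(sine) == pytest.approx(10 * np.log10(1 / np.sqrt(2)), abs=1e-3)

    def test_silent_audio_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            rms_log(AudioStimulus(samples=np.zeros(10), fs=1000.0))


class TestFdrBh:
    def test_all_small_pass(self):
        assert fdr_bh(np.full(64, 0.001)).all()

    def test_all_large_fail(self):
        assert not fdr_bh(np.full(64, 0.9)).any()

    def test_hand_executed_step_up(self):
        # p sorted {0.01, 0.02, 0.03, 0.5}: 0.03 <= (3/4)*0.05 so the first
        # three pass, 0.5 > 0.05 fails
        mask = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))
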