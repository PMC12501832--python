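# Methods

This note documents the models, estimators and numerical choices behind
`envtrf`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Forward TRF model

The encoding model is linear and time-invariant per channel:

    y_c[t] = Σ_b Σ_ℓ w[ℓ, b, c] · s_b[t − ℓ] + β_c + ε_c[t]

with lags ℓ spanning −100..1000 ms.  Lag samples are obtained by symmetric
rounding of `t_ms · fs / 1000` at both window ends; at 128 Hz this gives
lags −13..128, i.e. 142 lag columns per feature band.  The design matrix
holds each band delayed by each lag (zero-padded outside the track) plus a
constant bias column.

**Ridge estimation.** `W = (XᵀX + λM)⁻¹XᵀY`, where `M` is the identity
over lag columns and zero for the bias column (the intercept is never
penalised).  The system is solved from the accumulated per-track Gram
matrices (`XᵀX`, `XᵀY`), which makes cross-validation folds, the λ grid
search and the permutation null reuse the same accumulations; for cohorts
in which every subject hears the same stimuli the design-side Grams are
shared across all recordings.  A singular system at λ = 0 raises an error
advising a larger λ.

**λ selection.** One λ per participant (per condition), maximising the
mean leave-one-track-out CV correlation over all channels and folds, on a
log grid 10⁻²..10⁶ (9 values) by default; ties break toward the larger λ
(more smoothing at equal fit).  On noise-free data the selected λ is the
grid minimum, as regularisation can only bias an exactly identifiable
solution.

**Prediction accuracy.** Leave-one-track-out: for each fold the model is
fitted on all remaining tracks and the held-out track's EEG is predicted;
accuracy is the per-channel Pearson r, averaged over folds with a plain
arithmetic mean (not Fisher-z).  Folds with a zero-variance observed
channel record that channel as missing and are excluded from its mean with
a logged warning.

**Chance level.** 100 permutations by default; each permutation re-pairs
stimulus tracks with EEG tracks by a random derangement (no track keeps
its own stimulus) and reruns the full CV.  Re-pairing (rather than
circular shifting) preserves both marginal spectra exactly.  The matched
λ is reused for the permutations; re-selection per permutation is possible
but costly and changes nothing qualitatively.

**Data-amount curves.** Estimation is rerun on the first k tracks of each
session (presentation order, same k for both sessions), k = 3..n, feeding
the ICC-by-data-amount analysis.

## Stimulus features

* **Broadband envelope**: zero-phase 4th-order Butterworth band-pass
  250–8000 Hz, magnitude of the analytic (Hilbert) signal, compression by
  `x^0.6` (an inner-ear compression approximation), anti-aliased polyphase
  resample to the EEG rate.  The compression→resample order matters only
  at the third decimal; compression first is used throughout.  The
  broadband envelope is left unscaled by default (a z-score flag exists).
* **Multiband envelope**: eight gammatone bands (scipy's 4th-order
  all-pole IIR approximation), centre frequencies equally spaced on the
  ERB-number scale `E(f) = 21.4·log10(4.37 f/1000 + 1)` with endpoints
  250 and 8000 Hz (spacing 3.776 Cams); per band the same
  magnitude→compression→resample chain, then z-scoring per band.  For
  multi-track stimuli the z-score statistics are pooled over the
  concatenated tracks so that CV folds share one scale.
* **Derivatives**: signed first difference scaled by the sampling rate,
  length-preserved by a leading zero.  The first difference estimates the
  derivative at the inter-sample midpoint (half-sample latency); at 128 Hz
  and syllabic rates the amplitude error is < 0.1%.  Half-wave
  rectification (onset envelope) is available but off by default.

## EEG conditioning

Stage order: resample to 128 Hz → 1–15 Hz band-limit → bad-channel
replacement → artifact hook → epoching → referencing → analysis band →
pooled z-scoring.

* The 1–15 Hz stage uses Hamming windowed-sinc FIR filters with the
  rate-specific orders 846 (high-pass, 1 Hz) and 212 (low-pass, 15 Hz)
  at 128 Hz.  All FIR stages are applied forward–backward, which doubles
  the effective order and squares the magnitude response; this is accepted
  and is why pass-band gains sit within a couple of permil of 1 while
  stop-band attenuations are extreme.
* Analysis bands delta (1–4), theta (4–8) and full (1–8 Hz) use windowed-
  sinc band-passes with order from the 3.3/Δf rule at 1 Hz transition
  width.  Band filters apply to the EEG only, never to stimulus features.
* **Bad channels**: the activity statistic is the channel log-RMS; a
  channel is flagged when its z-score against the distribution of channel
  log-RMS exceeds 3.  A leave-one-out scaling was evaluated and rejected:
  its t-inflation flags channels on perfectly homogeneous recordings.
  With the include-self z-score a single extreme channel saturates the
  statistic near `(n−1)/√n`, so detection power requires ≳ 12 channels;
  at the 64-channel default this is immaterial.  Flagged channels are
  replaced by the mean of their index-adjacent good neighbours, rescaled
  to the neighbours' average RMS (a no-op for correlated neighbours;
  prevents the √2 variance shrinkage of averaging independent ones).
  This replaces spherical-spline interpolation, which needs a real
  electrode montage.
* **Artifact hook**: burst-artifact suppression and ICA-based rejection
  require genuine artifacts and manual inspection; a no-op hook preserves
  their position in the stage order for synthetic data.
* **Referencing**: average mastoid subtracts the mean of the two mastoid
  channels; the common average reference subtracts the instantaneous
  channel mean and is computed from mastoid-referenced data (the order
  used in practice).  Both are linear and idempotent.
* **EEG z-scoring** (estimation stage): each participant's channels are
  standardised by one affine map using the grand mean/SD pooled over all
  channels and samples, preserving between-channel amplitude ratios.

## Reliability statistics

**ICC(A,1)** (two-way model, absolute agreement, single measurement): from
the subjects × sessions ANOVA mean squares,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)) .

The p-value is one-sided for H₀: ICC = 0 from F = MSR/MSE on
(n−1, (n−1)(k−1)) df; the 95% CI is the standard F-based construction with
a Satterthwaite df for the absolute-agreement case.  Negative estimates
are reported as computed and labelled "poor".  Interpretation bins:
excellent > 0.90, good 0.75–0.90, moderate 0.50–0.75, poor < 0.50, with
boundary values taking the higher category.  The implementation is checked
in the tests against a loop-written ANOVA oracle (1e-10) and against
pingouin's independent implementation.

**TRF time-course ICC**: per lag in −50..950 ms (window edges converted to
integer lags by the same rounding rule as the design matrix, giving 129
lags at 128 Hz), the subjects × 2 table of TRF weights at one channel is
assembled and ICC(A,1) computed, with its per-lag F-based CI.  A bootstrap
CI would be an alternative; the F-based CI was chosen for determinism and
speed.

**Bland–Altman**: per-subject session-1 − session-2 differences; mean,
sample SD, and mean ± 1.96·SD limits of agreement, plus the per-subject
(mean, difference) plotting payload.

**SNR** is RMS over the concatenated 0..65 s post-stimulus windows divided
by RMS over the −5..0 s pre-stimulus windows, per channel.  **Intensity**
is 10·log₁₀(RMS) of the stimulus waveform.  **FDR** masks use
Benjamini–Hochberg step-up at q = 0.05 (delegated to statsmodels).
Mixed-model fits on the emitted tidy tables are intentionally out of
scope; the long-format accuracy CSV carries exactly the columns such
models consume.

## Synthetic cohorts

The generator inverts the forward model, so estimation can be validated
against known truth:

    eeg_c[t] = topo_c · (kernel ∗ bbenv)[t] + noise_sd · pink_c[t]

* **Stimuli**: pink-noise carrier, amplitude-modulated by a half-wave
  rectified sum of four sinusoids with frequencies drawn in 3–5 Hz and
  random phases — placing the envelope modulation peak at syllabic rates
  (2–8 Hz), where natural speech envelopes carry most energy.  Real
  speech differs in many ways that do not matter for these tests
  (spectral tilt dynamics, pauses, linguistic structure); what the tests
  validate is the estimation and reliability machinery, not speech
  acoustics.
* **Kernel**: difference of two unit-peak gamma pulses (shapes 3 and 4,
  scales 40 and 60 ms; positive peak ≈ 80 ms, trough ≈ 180 ms), cosine-
  tapered to zero over 400–500 ms so the support is exactly [0, 500] ms —
  inside the −100..1000 ms estimation window.
* **Topography**: fixed raised cosine over channel index peaking at the
  vertex ("Cz") channel, floor 0.1 — a frontocentral emphasis without head
  geometry.
* **Variability dials**: per-subject amplitude gain `1 + N(0, bs²)` and,
  for session 2 only, a further multiplicative `1 + N(0, ss²)` (gains
  floored at 0.1).  Latencies are fixed, keeping the variance structure of
  any amplitude-linear downstream measure analytically controllable:
  the between-subject variance component is `bs²` and the within-subject
  component is `ss²/2` (session 1 carries no session draw).
  `spec_for_accuracy_icc(ratio)` inverts this for a target variance ratio.
* **Noise**: 1/f-amplitude noise, independent across channels, unit SD
  scaled by `noise_sd`.  The default `noise_sd = 1` puts single-channel
  accuracies near 0.3–0.5 on 65 s tracks — a sensitive operating point on
  the amplitude→accuracy curve.
* **Layout**: tracks are separated by 6 s noise-only gaps so every epoch
  has its −5 s baseline; onsets are recorded as events.  Generation is a
  pure function of the spec: seeds fan out through named
  `SeedSequence(seed, spawn_key=(stage, subject, session))` substreams, so
  cohorts are bit-reproducible and adding subjects or sessions never
  perturbs existing ones.

### What the synthetic validation does and does not show

Passing tests show the estimator recovers known kernels, that accuracy and
its reliability respond to the variance dials as designed, and that the
statistics are correct as implementations.  They do not show that real
EEG satisfies the linear-time-invariant assumption, that real artifacts
are handled (the ASR/ICA stages are no-ops here), or that effect sizes
match any particular dataset.

## Problem sizes and numerical choices

* Kernel recovery uses the direct path (simulated recording → TRF at
  λ = 10⁻⁸) rather than routing through the band filters: filtering the
  EEG but not the feature convolves the estimated kernel with the filter,
  which is expected behaviour, not an estimation error, and would blur a
  ground-truth comparison (measured: recovery r drops from 1.000 to
  ≈ 0.978 through the 1–8 Hz chain).  Filter correctness is validated
  separately by frequency-response tests.
* The variance-ratio recovery analysis uses 30 subjects × 2 sessions,
  3 tracks × 15 s, 32 channels, channel-mean accuracy at fixed λ = 100,
  20 seeds per target ratio (12 in the acceptance script).  Sizes were
  chosen so the cross-validation measurement noise of the channel-mean
  accuracy (SD ≈ 0.005–0.007) is an order of magnitude below the designed
  amplitude-driven spread; the small negative bias of the ICC point
  estimate at n = 30 remains visible (e.g. ≈ 0.70 measured at a designed
  ratio of 0.8) and is well inside the ±0.15 recovery band.
* The data-amount analysis uses 10 subjects, 12 tracks × 15 s,
  `noise_sd = 3`, Cz accuracy: at k = 3 the measurement-noise share of the
  within-subject variance is large, so the ICC roughly doubles from k = 3
  to k = 12 — the qualitative rise-then-plateau that motivates collecting
  ≳ 6–12 one-minute segments.
* Ridge systems are solved with a symmetric positive-definite solver on
  the Gram form; tolerances in tests reflect that path (1e-8 against
  explicit normal equations).  ICC of a constant table raises (zero total
  variance); the constancy check is exact, not tolerance-based, so tables
  of numerically tiny TRF weights are still analysed.
* CSV output uses a fixed `%.10g` float format, making reruns of the same
  config byte-identical (the manifest contains no timestamps).

## Known limitations

* The neighbour-mean channel replacement is index-based; with a real
  montage a spatial interpolation should replace it.
* Bad-channel detection has limited power below ~12 channels (statistic
  saturation) and, like any fixed 3-SD rule, flags an occasional good
  channel at 64 channels; replacements are benign.
* The generator varies kernel amplitude only; latency or shape drift
  between sessions — plausible in real data — is not modelled, so
  TRF-time-course ICC on synthetic data is optimistic by construction.
* The EEGLAB `.set` reader covers continuous recordings with standard
  fields (scipy path for classic MAT files, MNE for v7.3); epoched `.set`
  structures are out of scope.
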