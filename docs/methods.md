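# Methods

This note records the modeling choices behind `eegquad`: what each stage
assumes, which parameters matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Problem setting

A panel of subjects watches a set of videos. Each subject rates each video on
four 1–9 scales — Valence (pleasantness), Arousal (activation), Dominance
(sense of control), Liking — and EEG is recorded during viewing. The target
of inference is *per video*, not per viewing: the quadrant of the
valence–arousal plane that the video dominantly induces across subjects
(HVHA = happy, HVLA = relaxed, LVHA = fearful, LVLA = sad). Classification is
evaluated subject-independently: no subject appears in both a training fold
and its test fold.

## Label calibration

**Normalization.** Z-scores use the population-SD convention (ddof 0)
throughout, so tests can assert exact values. Two scopes exist and are kept
separate deliberately: the clustering route normalizes per subject across
that subject's videos (removing individual scale usage), while the
borderline-refinement rule uses an independent global z-score per dimension
over all (subject, video) samples. Constant groups map to zeros rather than
NaN.

**Calibrated route.** Quadrants are assigned from the signs of (z_V, z_A);
samples with |z_V| < 0.1 have their valence side re-decided by the sign of
z_L, and |z_A| < 0.1 defers the arousal side to z_D. The pairing — liking
resolves valence, dominance resolves arousal — follows the psychological
alignment of liking with pleasantness and dominance with activation/control,
and is isolated in one function so an alternative pairing is a one-line
change. The per-video label is the mode over subjects; its consistency is
the modal share; a subject's conformity is the fraction of videos where they
agree with the group. Ties resolve to the lowest quadrant code (HVHA first)
and are flagged — determinism over cleverness.

**Clustering routes.** K-means (15 restarts), a Gaussian mixture (four
components, full covariances, 15 restarts, covariance regularizer 1e-6) and
Ward-linkage hierarchical clustering run on per-video PCA scores: each
video's subjects × 4 matrix is decomposed, the smallest k reaching 95%
cumulative explained variance is kept (padded with zeros to 4 columns), and
scores are pooled across videos. Clusters are mapped onto quadrants by brute
force over all 24 bijections, maximizing mean cosine agreement between
cluster centroids in (z_V, z_A) and the sign prototypes (±1, ±1); a
degenerate clustering (< 4 non-empty clusters) falls back to
nearest-prototype per observation and is flagged. Note a structural
consequence: per-video PCA centers each video's matrix across subjects, so
the pooled scores carry mostly *within-video* (between-subject) variation and
only weakly encode the video's own quadrant. The clustering routes therefore
recover planted labels well above chance but far below the calibrated route —
the same ordering the calibrated strategy is designed to fix. On a zero-noise
panel the per-video matrix is constant and clustering is degenerate; the
zero-noise recovery guarantee (100%) belongs to the calibrated route.

**Threshold baseline.** V > 5 → high valence, A > 5 → high arousal; a rating
exactly at the midpoint counts as the low side (documented tie rule).

## Signal cleaning

Order is fixed: band-pass → common average reference → ICA → wavelet
denoising; every stage preserves the channels × samples shape.

* **Band-pass**: 4th-order Butterworth, 1–45 Hz, applied forward–backward
  (zero phase). The effective magnitude response is the squared design
  response; phase linearity matters because coherence features downstream
  would otherwise be distorted. The high cutoff is configurable; note that a
  45 Hz cutoff forecloses most of the 30–60 Hz γ band, so γ shares of a
  filtered signal mostly reflect the 30–45 Hz remainder. Band-power analysis
  can be run on unfiltered epochs where full γ coverage is wanted.
* **CAR**: subtracts the instantaneous channel mean; cross-channel sums are
  zero afterwards and the operation is idempotent.
* **ICA artifact gating**: FastICA with as many components as channels;
  components with kurtosis above 5 (plain convention, Gaussian = 3; the
  excess convention is a config switch) are zeroed, at most four of them,
  ranked by kurtosis. Blinks are sparse high-amplitude transients and hence
  heavy-tailed, which is what the gate keys on. FastICA's iteration-limit
  criterion routinely fires on near-Gaussian backgrounds even though the
  heavy-tailed components are extracted reliably; that condition is flagged
  in the removal report but does not abort removal. A hard failure returns
  the epoch unmodified.
* **Wavelet denoising**: per channel, 4-level db4 decomposition; the noise
  scale is the MAD of the finest detail level divided by 0.6745; each detail
  level gets a soft threshold minimizing Stein's unbiased risk estimate,
  capped by the universal threshold √(2 ln n). A zero threshold is applied
  as the identity. Energy never increases on noise-only input.

## Band-energy ratios

Bands are half-open: δ [1,4), θ [4,8), α [8,14), β [14,30), γ [30,60) Hz;
they partition the 1–60 Hz denominator range exactly, so the five shares of
any channel sum to 100%.

* **FFT path**: Welch spectra (4 s Hann segments, 50% overlap); band energy
  integrates the PSD over the band.
* **Wavelet path**: an analytic Morlet (`cmor1.5-1.0`) scalogram on a 1 Hz
  grid over [1, 60); band energy sums |W(f,t)|². Because a constant-Q wavelet
  has frequency-proportional bandwidth, the raw grid summation over-weights
  low frequencies (a 2 Hz and a 20 Hz tone of equal power would split roughly
  62/37). By default each grid frequency's contribution is therefore divided
  by the scalogram's measured energy response to a unit sinusoid at that
  frequency (computed once per sampling rate and cached), flattening the
  response so equal-power narrowband components receive equal energy. The
  raw summation is available via `gain_calibration=False`.
* **Aggregation**: epochs of a class are reduced to one representative
  signal by the point-wise median (even counts take the midpoint mean), and
  spectra are estimated on that representative; the alternative order
  (median of per-epoch spectra) is behind a flag. Subject selection keeps
  subjects whose conformity strictly exceeds the panel mean; if none
  qualifies (all equal), all are kept with a warning.

## Feature families

All features are named `family_electrode_band_statistic` and carry a schema
entry. Core width is 20 + 5 + 14 + 110 = 149; label and subject-id ride along
as separate non-feature columns.

* **Wavelet energies** (20): five band shares at FP1, C3, T8, O1.
* **Coherence** (5): magnitude-squared coherence of F3–C4 from 2 s Hann
  segments at 50% overlap, averaged over in-band frequency bins. Estimation
  from a single segment is refused — the estimator degenerates to 1
  identically. For independent signals the estimate has a positive
  small-sample bias of roughly 1/(number of segments).
* **Time-domain** (14): per electrode in {FP1, FP2}: median of the signed
  band-passed signal and peak |amplitude| in α, β and the 1–45 Hz broadband
  (12 values), plus the full-signal mean squared deviation (2). "Peak" means
  maximum absolute value; "median" is of the signed signal. Note that
  dispersion-type statistics of a *constant* channel are zero and its
  band-passed median/peak are near zero — there is no in-band amplitude to
  report.
* **PSD** (110): sliding 4 s windows at a 2 s step; within each window a
  Welch estimate (2 s sub-segments, 50% overlap); per electrode and band the
  across-window mean and maximum of in-band mean power.

Scale behavior, asserted by test: energy-ratio and coherence families are
amplitude-invariant; time-domain amplitudes scale linearly; MSE and PSD
scale quadratically.

## Selection and classifiers

Engineering: features are z-scored within each subject (leakage-free by
construction — only a subject's own statistics are used), then augmented
with first-order differences along the feature axis (width 2n − 1).

* **mRMR**: greedy MID criterion (relevance minus mean redundancy), mutual
  information on 5-bin equal-frequency discretizations; deterministic, ties
  break by column order. Top 80 retained.
* **Chi-square**: scores on binned non-negative codes.
* **ReliefF**: 10 nearest hits/misses per probe, every observation a probe,
  range-normalized L1 distances, miss contributions weighted by class prior.
* **Fusion**: ascending mean of the three rank positions, ties broken by the
  mRMR position; the top 8 features survive. The default pipeline nests the
  two stages (mRMR-80, then fused-8); both stages are refit *inside each
  training fold* of cross-validation. Selecting once on pooled data would
  leak label information into the test folds and lift the permuted-label
  baseline above chance, which defeats the point of a chance control.

Classifiers: RBF-SVM with one-vs-one decomposition and kernel scale
1/n_features ("auto"); a 200-tree random forest whose per-tree complexity is
capped at 20 internal splits (enforced as a 21-leaf maximum); and a dense
256-128 network with ReLU, batch normalization and dropout 0.5 after each
hidden layer, softmax/cross-entropy output, Adam at 1e-3, batch 32, up to
100 epochs with early stopping on a 10% validation split — implemented
directly on NumPy and fully seeded. Evaluation offers both five-fold
subject-independent CV (the primary protocol) and a 70/30 stratified split
whose class balance is checked by a chi-square homogeneity test (p > 0.05
expected for a well-matched split). Per-class recall/precision/F1 and the
confusion matrix are reported; a class never predicted gets precision 0 with
an explicit flag.

## Synthetic data

The generator emulates the study conditions, not physiology:

* **Ratings**: 32 subjects × 40 videos by default; each video carries a
  planted quadrant (balanced cycle), with prototype (V, A) at
  (7,7)/(7,3)/(3,7)/(3,3) and midpoint 5 separating the quadrants. Ratings
  scatter with i.i.d. noise (default SD 1.0) plus a per-subject bias
  (default SD 0.5); Dominance tracks arousal and Liking tracks valence with
  correlation 0.6, giving the refinement rule genuine signal. Scores clip to
  [1, 9].
* **EEG**: per (subject, video), a sum over the five bands of unit-RMS
  band-limited Gaussian noise scaled by a class-dependent gain (default:
  each class boosts one band by 3× — HVHA→θ, HVLA→α, LVHA→β, LVLA→δ), plus
  unit-RMS 1/f background and optional blink transients: 0.5 s raised-cosine
  pulses at 5× the background SD, frontally weighted (FP1/FP2 1.0, F3/F4
  0.5, others 0.1), arriving at 2 events/min by default (Poisson). Default
  montage is the 11-channel set at 128 Hz for 60 s.
* **Determinism**: identical (design, seed) gives bit-identical output; EEG
  epochs are seeded per (subject, video) so any subset regenerates
  identically.

What this does *not* emulate: volume conduction and channel covariance
structure, non-stationarity within an epoch, subject-specific spectra,
muscle/line-noise artifacts, or any dipole/forward model. Passing tests
therefore demonstrate that the pipeline recovers planted band-structure and
rating-structure under controlled conditions — not that comparable accuracy
would be achieved on recorded EEG, where reduced-channel cross-subject
four-class accuracy is known to sit far lower.

## Problem sizes and numerical conventions

The end-to-end experiment used by the test suite and the acceptance script
runs 20 subjects × 20 videos with 10 s epochs on the 11-channel montage —
large enough for five subject-independent folds and stable selection, small
enough to run comfortably on a single CPU. The permuted-label baseline
repeats the full selection + CV procedure 20 times with shuffled labels.
Wavelet shares use the calibrated scalogram; silhouette scores are computed
in the clustered space; even-length medians take midpoint means; all
regularization constants, window lengths and thresholds above live in
`PipelineConfig` and are printed by `eegquad show-config`.

## Known limitations

* The feature layout fixes the core width at 149 (= 20 + 5 + 14 + 110); the
  time-domain family's internal layout is one defensible reading of
  "median and peak amplitudes with emphasis on α and β" and is isolated in a
  single schema constant.
* The DEAP reader targets the preprocessed release layout (pickled
  trials × channels × samples with a 3 s pre-trial baseline, dropped by
  default); raw BDF parsing is out of scope.
* The clustering labeling routes are structurally weak at video-level
  recovery (see above); they are kept for comparison, not recommended as the
  primary labeler.
* With the default 1–45 Hz band-pass, γ-band quantities reflect only the
  30–45 Hz remainder of the band.
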