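# Methods

## Problem and pipeline

`emgrasp` classifies which of six prehensile patterns (spherical,
tripod, power, lateral, tip, extension) a reaching movement is heading
toward — and, within a grasp, whether the target object is light or
heavy — from multi-channel surface EMG recorded at 1,000 Hz from the
upper arm and trunk (deltoid middle, biceps, triceps, latissimus dorsi,
trapezius, pectoralis; optionally plus the forearm wrist flexor and
extensor). The motivation is myoelectric prosthesis control for users
who lack reliable below-elbow musculature.

The processing chain, in execution order:

1. **Amplitude normalization.** Each muscle is mapped through
   `(x − min)/(max − min)` with min/max pooled over a reference trial
   set. The default scope pools over *all* trials, matching the
   protocol this pipeline reproduces; this leaks test-fold amplitude
   range into training, so a `train_only` scope (min/max from the nine
   training folds, out-of-range test values clipped to [0, 1]) is
   provided. The leakage affects only the two scalar range statistics
   per channel, but users comparing methods should prefer `train_only`.
2. **Movement onset.** The trial clock is anchored to triceps activity:
   the subject presses a timer button to start each trial, which
   activates the triceps regardless of the upcoming grasp. Onset is the
   first sample where the causal 50-ms moving average of the rectified,
   baseline-mean-subtracted triceps signal exceeds (baseline mean +
   3 SD) and stays above it for ≥ 25 ms, with baseline statistics from
   the first 200 ms. The rule is invariant to per-channel affine
   normalization, so its placement before or after step 1 is
   immaterial. All four parameters live in `RunConfig`.
3. **Reach-phase truncation.** Samples `[onset, onset +
   round(f·(end − onset)))` are kept, with `f = 0.40` (able-bodied
   grasp timing) or `0.49` (prosthesis users). Time-normalization to
   0–100 % of the trial is bookkeeping only — no resampling — so the
   spectral content seen by the STFT is untouched.
4. **Windowing.** 400-sample windows, 50-sample step; count
   `⌊(L−400)/50⌋ + 1`.
5. **Spectrogram features.** Per window per channel: three
   Hamming-windowed frames (length 200, hop 100, starts 0/100/200),
   FFT length 256 → 129 one-sided magnitude bins × 3 time bins. The
   200/100/256 geometry is the unique natural choice producing 129
   frequencies and three time bins from a 400-sample window. The first
   95 frequency rows (≤ ~367 Hz) are kept, each channel plane is
   min–max normalized to [0, 1], and flattened frequency-major to a
   285-vector. Magnitude (not power, not dB) is used: the subsequent
   min–max normalization makes any monotone rescaling immaterial, and
   magnitude is the simplest choice.
6. **PCA and grid embedding.** One PCA per channel, fitted on training
   segments only, keeping 25 components. Component signs are fixed
   (largest-magnitude entry positive) for run-to-run identity. The 25
   scores fill a 5×5 grid center-out: positions sorted by Chebyshev
   distance from the center, ties broken row-major, so the most
   significant component sits at the center where 4×4 convolution
   kernels overlap most. Any fixed bijection would satisfy the design
   constraint ("most significant at the center"); this one is a
   declared convention chosen to maximize filter support for
   high-variance components. A joint-PCA ablation
   (`pca_per_channel=false`) treats the concatenated 285·C vector as a
   single channel.
7. **Compact CNN.** 5×5×C grid → conv 400 filters 4×4 (valid, stride
   1) → ReLU → flatten (1600) → fully connected 400 + ReLU with
   dropout 0.5 (training only) → K-way softmax; cross-entropy loss;
   SGD with learning rate 0.001, momentum 0.9, batch 32, 100 epochs,
   per-epoch reshuffling from an explicit seed. Implemented directly
   in NumPy (float32, im2col + GEMM); the forward pass is checked
   against a brute-force direct convolution in the tests. He-normal
   initialization; inverted dropout. An architecture-figure reading
   with a second 2×2 convolution stage (2×2×400 → 1×1×400) is gated
   behind `cnn_two_stage` and off by default; the single-conv reading
   follows the method description's layer list.
8. **TDAR–SVM baseline.** Per channel per window: MAV, ZC, SSC, WL and
   AR(4) Yule–Walker coefficients, concatenated channel-major
   (C·(4+p) features). Windows are [0, 1]-normalized, so each channel
   is mean-centered before feature computation — ZC of a non-negative
   signal is identically zero and the AR model is defined on the
   demeaned process. ZC/SSC thresholds default to 0.01 on the
   normalized amplitude scale to suppress noise-floor counts; AR order
   4 is the surface-EMG convention. Root-mean-square is deliberately
   absent: the baseline feature list is exactly MAV/ZC/SSC/WL/AR.
   Features are z-scored with training-fold statistics and classified
   by a one-vs-one RBF SVM (C = 1, `gamma="scale"`), with
   pairwise-coupling probability calibration so both classifiers share
   one predict contract. The SVM hyper-parameters are conventions (the
   protocol being reproduced does not state any); both kernel and C
   are configurable.
9. **Evaluation.** 10-fold cross-validation over segments, random
   disjoint folds with sizes differing by ≤ 1, the test fold rotating
   in order. The default `random_segment` mode mirrors the reproduced
   protocol; because overlapping windows of one trial can then land on
   both sides of a split, a `grouped_by_trial` mode is provided that
   never splits a trial. PCA, feature scaling and classifiers are
   always fitted on the nine training folds only. Reported: per-fold
   accuracies, mean ± SD (SD across folds, ddof = 1), and a
   true-rows × predicted-columns confusion matrix (counts and
   row-normalized). Cross-subject inferential statistics (normality
   tests, repeated-measures ANOVA) are out of scope; the per-fold
   accuracy tables written by `report` feed any external statistics
   package.

## Synthetic data generator

No public recordings exist for this protocol, so the generator
emulates its structure: 6 grasps × 2 weights × 10 repetitions per
dataset, 6 or 8 channels, 3-s trials at 1,000 Hz with a ≥ 200-ms
quiescent pre-onset baseline (default 300 ms).

Surface EMG is modelled as amplitude-modulated band-limited Gaussian
noise — the standard interference-pattern surrogate that reproduces
the first- and second-order statistics amplitude and spectral features
respond to. Per muscle: a unit-variance carrier (white noise through a
4th-order zero-phase 20–450 Hz Butterworth band-pass) is scaled by a
deterministic activation envelope, mixed linearly with anatomically
adjacent channels (crosstalk 0.1, making per-channel PCA non-trivial),
and summed with an independent band-limited noise floor (default SD
0.05 relative to unit gains).

Envelopes implement a class-specific muscle synergy: a fixed 6×C gain
matrix (rows pairwise distinct in ≥ 2 channels, every row with a gain
> 0.2), per-muscle activation lags of 0–420 ms after onset, a
class-specific rise time (150–350 ms), and a slow class-specific
sinusoidal modulation (1.5–4 Hz, depth 0.25, per-muscle phase) standing
in for reach kinematics. The modulation matters: per-segment per-channel
spectrogram normalization erases absolute amplitude, so the CNN's class
information lives in the temporal envelope pattern across the three
STFT bins, which the lags, ramps and modulation make class-distinct.
The triceps additionally receives a class- and weight-independent
"button-press" burst at onset (gain 0.6, 100-ms rise, 500-ms decay),
reflecting the self-timed protocol in which every trial starts with the
same button push — this is what makes the onset anchor reliable for
classes whose own triceps involvement is weak. Heavy objects multiply
the class envelope by 1.6 and delay non-triceps activation by 60 ms,
giving the weight task both an amplitude cue (used by TDAR features)
and a timing cue (surviving spectrogram normalization).

Determinism: a dataset is a pure function of its spec; per-trial seeds
derive from the dataset seed and the trial's labels through
`numpy.random.SeedSequence`.

What the generator does *not* model: motor-unit recruitment and firing
statistics, electrode lift-off and motion artifacts, inter-subject
anatomical variability, amputee-specific signal degradation beyond the
noise/gain knobs, and non-stationarity across repetitions. Synthetic
classes are far more separable than real inter-subject EMG: both
methods reach ~100 % on the default dataset, where the original
subject recordings yielded 60–84 %. Passing tests therefore certify
the pipeline's mechanics (shapes, contracts, determinism, leakage
discipline, learnability), not field performance on real recordings.

A practical limit of the onset rule under the default threshold
(mean + 3 SD, 25-ms hold): when the baseline noise floor approaches
the burst amplitude (noise SD ≳ 0.3 here), some trials legitimately
yield no detectable onset and the pipeline reports a no-onset error
rather than guessing. Noise-robustness checks of the classifiers
therefore sweep the floor within the detectable range, and the
separation-degrades-with-noise property of the generator is verified
directly on features.

## Numerical choices

- Trial CSV serialization uses 17 significant digits, so write→read
  round-trips float64 bit-exactly.
- `round()` (banker's rounding) defines the truncation length; window
  indexing is 0-based with half-open intervals.
- PCA uses a full SVD (deterministic); orthonormality is asserted to
  1e-8 in tests.
- CNN arithmetic is float32; forward-pass oracle equivalence is tested
  in float64 at 1e-6.
- A constant spectrogram plane (no spectral contrast) normalizes to
  zeros with a warning; a constant raw channel is a hard error naming
  the muscle.
- Softmax is computed with max-subtraction; argmax ties resolve to the
  lowest class index.
- Cross-validation accuracy is the unweighted mean of per-fold
  accuracies; with fold sizes differing by ≤ 1 it matches the
  confusion-trace ratio to within 1 %.

## Problem sizes used in the shipped checks

The acceptance script and the heavy tests run the full default
conditions: 120 trials × 14 windows ≈ 1,680 segments, 10-fold CV, 100
training epochs. Unit tests of the CV plumbing use a reduced dataset
(24 short trials, 5 folds, 20 epochs) — those sizes test contracts,
not performance claims.
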