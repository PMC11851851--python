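# Methods

## Problem and pipeline

`painsense` classifies trial-level pain from multichannel EEG. A trial is an
8–12 s epoch starting at an event marker that encodes the subject's 1–10
pain rating as `10000 + rating`. Two label schemes are supported: binary
(rating ≤ 5 → `no_pain`, > 5 → `pain`) and ternary (≤ 3 `low`, 4–6
`moderate`, > 6 `high`). The stage order is fixed: high-pass → notch →
downsample → ICA → epoching → wavelet-statistical features → (training-only)
augmentation and balancing → classification.

## Preprocessing

* **High-pass, 1 Hz** — 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) so it is zero-phase: epochs keep their latency structure.
  The filter family and order are implementation choices; the cutoff is the
  pipeline's defining parameter.
* **Notch, 50 Hz** — IIR notch with quality factor 30 (≈1.7 Hz −3 dB width
  at 50 Hz), also zero-phase. Tones ≥ 5 Hz away pass within 1 dB.
* **Downsampling, 1000 → 500 Hz** — polyphase resampling
  (`resample_poly`), which applies its own anti-alias filter; output length
  is `floor(n · target/fs)`.
* **ICA** — extended Infomax (via `mne.preprocessing.infomax`) after PCA
  whitening, with `n_components` defaulting to the channel count. The
  unmixing matrix is fitted on up to `ica_max_samples` (default 20 000)
  evenly spaced timepoints and applied to the full recording; this keeps
  62-channel fits tractable on one CPU while the mixing geometry, which is
  time-invariant in the model, is estimated from a representative sample.
  Rank-deficient data raise an error advising component reduction.
* **Artifact rule** — the reference data's component rejection appears to
  have been a manual judgement, so the automatic default here is a
  pluggable stand-in: a component is rejected when its kurtosis z-score
  across components exceeds 3 (spiky, blink-like activity) or when it
  correlates > 0.8 with its own < 1 Hz low-passed copy (drift-dominated).
  Both thresholds are configurable; explicit index sets and callables are
  accepted. Rejecting every component is refused.

## Features

Each epoch channel is decomposed with a level-5 Daubechies-4 DWT
(symmetric signal extension — stated because coefficient counts depend on
it), giving bands A5, D5…D1. At 500 Hz these approximately cover 0–7.8,
7.8–15.6, 15.6–31.2, 31.2–62.5, 62.5–125 and 125–250 Hz, so D5/D4 straddle
the alpha and beta rhythms where rating-conditional power differences are
injected by the generator and expected physiologically.

Ten statistics are computed per band, in fixed order: zero-crossing rate,
5/25/75/95th percentiles, mean, median, standard deviation, variance, RMS.
Conventions that differ between packages are pinned here:

* zero-crossing rate = strict sign changes / (n − 1), zeros counted as
  positive, hence always in [0, 1];
* percentiles use linear interpolation; the four-element percentile set is
  configurable (four symmetric percentiles capture spread and tails);
* SD and variance are population moments (ddof = 0), so
  RMS² = mean² + variance holds exactly, which the tests assert.

Feature rows are channel-major (`channel__band__statistic`), one row per
epoch; 62 channels give 62 × 6 × 10 = 3720 columns regardless of epoch
duration. No scaling happens here — standardisation is fitted inside the
classifier stage on training data only.

## Augmentation

Three transform operators expand a training set six-fold (originals plus
five variants per sample), followed by SMOTE balancing:

* **Multiplication** — `x · (1 ± C_mult)`, `C_mult = 0.05`.
* **Noise injection** — uniform noise on [−0.5, 0.5] scaled from the data's
  standard deviation. The governing constant is stated as a formula factor
  in one place and as "noise SD = 2 % of the training-data SD" in another;
  these disagree by the SD of the uniform distribution (1/√12). The default
  `target_sd` mode honours the 2 % statement exactly (the tests verify the
  realised SD to ±10 % over 10⁵ draws); `formula_literal` mode applies
  `rand · σ · C_noise` verbatim for comparison. σ is the pooled training-
  partition SD by default (`noise_sigma_scope="sample"` is available).
* **Frequency shift** — analytic signal by Fourier transform with doubled
  positive frequencies (Hilbert transform), multiplied by
  `exp(±2jπ·C_freq·t)`; the real part is returned. `C_freq` is in Hz
  (0.2 by default): with `t` in seconds the exponent is a phase in cycles.
  Shifting by `+c` then `−c` returns a mid-band tone within 2 % RMS.

Frequency shifting needs a time axis, so the default augmentation space is
the epoch signal before feature extraction; a feature-space mode exists for
tabular workflows and treats the column index as a unit-spaced axis.

**SMOTE** brings every class up to the majority count: each synthetic point
is `x + u·(x_nbr − x)`, `u ~ U[0,1]`, with `x_nbr` one of the k = 5 nearest
same-class neighbours (Euclidean; k is not documented for the reference
procedure, 5 is the canonical default). Originals are preserved verbatim;
singleton classes are an error; k is clamped (with a log message) when a
class has fewer than k + 1 members.

Both stages run strictly inside training partitions. In the epoch-level
experiment runner the six variants of every epoch are computed once per
run — they depend only on the epoch and the run seed, never on the fold —
and each fold's training set is assembled from the variants of its training
epochs only. This is arithmetically identical to re-running the transform
inside every fold while avoiding repeated feature extraction; test epochs
contribute only their original rows, and a `LeakageGuard` carrying the
fold's test indices is checked by every training-only stage.

## Classifiers

* SVM: RBF kernel, C = 1.0, gamma = "scale". By default, class
  probabilities are a softmax over the decision values rather than Platt
  scaling (`platt=True` restores it): Platt's internal cross-validation
  quintuples fit cost and affects only the probability-based RMSE metric,
  not the label metrics.
* k-NN: k = 3, Euclidean. Random forest: 100 trees, Gini.
* CNN: 1-D convolutions over the ordered feature vector (the features are
  tabular, not images): two conv blocks (32 then 64 filters, kernel 3,
  ReLU), each followed by max-pooling (2) and dropout 0.25; flatten; dense
  128 and 64 (ReLU) with dropout 0.5 and 0.3; softmax output of width 2 or
  3. Filter counts and kernel sizes are package defaults, configurable.
* RNN: stacked LSTM layers (tanh), default 128 → 64 units (within the
  64–256 range found effective; counts outside 32–512 trigger a warning),
  dropout 0.3 after each LSTM layer, a dense ReLU layer, softmax output.
  The flat feature vector is folded into a sequence of
  (bands × statistics) steps with one feature per channel at each step
  (`n_channels` hyperparameter); an arbitrary `(T, D)` reshape is also
  supported. The tensor layout is not externally pinned; this folding
  gives the LSTM a plausible within-channel progression axis.
* Both neural families train with minibatch Adam on categorical
  cross-entropy (CNN default learning rate 9 × 10⁻⁵ over 100 epochs; RNN
  default 100 epochs binary / 50 ternary). They are implemented directly
  in numpy (`_nn.py`: im2col convolution, BPTT LSTM, inverted dropout,
  Adam) with every stochastic element drawn from one seeded generator, so
  results are reproducible on a fixed platform; bitwise cross-platform
  identity is not promised.
* Grid search over dropout rate, learning rate
  ({0.2, 0.5, 0.05, 0.005, 0.009, 0.0009, 0.00009}) and epoch count
  ({50, 80, 100, 120, 200}) scores members by mean stratified-k-fold
  validation accuracy (a single validation split is also supported, since
  the reference procedure does not say which was used); ties resolve to
  the earlier grid member, and the full results table is returned.

## Evaluation

Holdout uses a stratified 80:20 split; k-fold uses stratified k = 10 by
default (stratification defaults on because the labelling schemes are
imbalanced; unstratified splitting is available). Metrics: accuracy;
precision/recall/F1 as positive-class values for the binary scheme
(positive = `pain`) and macro averages for the ternary scheme (the
averaging rule is not externally derivable; macro is the symmetric default,
micro/weighted are accepted); RMSE between predicted probability rows and
one-hot labels, the natural companion of a cross-entropy-trained softmax.
Mean metrics are reported across folds together with per-fold values,
confusion matrices, augmentation bookkeeping and the leakage-audit
counters.

## Synthetic data

`generate_recording` emulates the assumed session structure: ~1000 Hz
sampling, a 62-channel default montage, `Comment` markers at epoch onsets,
variable 8–12 s epochs with 1 s silent guard gaps, and per-epoch alpha
(10 Hz) and beta (20 Hz) sinusoids with random phases whose amplitudes grow
with the pain rating (`band_effect`: scalar slope or ten explicit
per-rating multipliers). Superimposed recording-wide: pink-ish background
noise (default SD 1 µV), a 50 Hz line sinusoid (default 2 µV) and a slow
0.05–0.3 Hz drift (default 10 µV) — one designed removal target per
preprocessing stage. Baseline rhythm amplitudes are 4 µV (alpha) and 2 µV
(beta), ordinary scalp-EEG magnitudes.

What it does **not** model: volume conduction and electrode geometry
(channels are statistically independent apart from sharing the line
frequency), inter-subject variability (all events are one pooled
population), non-stationary artifacts (blinks, EMG bursts), or 1/f
structure beyond the pink-noise approximation. Passing pipeline-recovery
tests therefore demonstrates that the implementation recovers the class
structure it is pointed at — not field performance on clinical recordings.

`generate_feature_table` provides Gaussian class blobs separated by
`effect_size` along a random direction, for worked examples and classifier
tests; `effect_size = 0` gives exchangeable classes (verified by a
permutation-test oracle).

## Problem sizes and numerical choices in the test suite

The end-to-end recovery test simulates 62 channels × 200 events (~37 min of
signal), preprocesses with the defaults (ICA fitted on a 20 000-sample
subsample), and evaluates all five families under 10-fold CV for both
schemes. The neural families run at 5 epochs with reduced capacity (CNN
8/16 filters, pool 4; single 64-unit LSTM) — scaled-down training budgets
chosen for single-CPU wall-clock, which is also why the recovery thresholds
(binary ≥ 0.85, ternary ≥ 0.70 for the best family) are carried by the
best family rather than demanded of every model; the observed run has the
tuned baselines and both networks well above them, and the per-family
accuracy ordering is reported rather than asserted.

Other numerical pins: DWT reconstruction must be exact to 1e−8 relative
error; zero-shift frequency modulation is the identity to 1e−8; SMOTE
synthetic points lie on parent–neighbour segments to 1e−8; ICA recovery of
a two-source mixture must reach |r| ≥ 0.95 up to permutation and sign.
Degenerate inputs are defined, not left to chance: zero-variance samples
pass through noise injection unchanged (logged), epochs shorter than the
level-5 minimum (224 samples) raise with the epoch named, empty rejection
sets reconstruct the identity, and already-balanced input passes through
SMOTE untouched.

## Known limitations

* The BrainVision reader covers the dialect the package writes
  (multiplexed IEEE float32, INI header, `Comment` markers) plus a
  delimited-text fallback — not the full format family (INT_16 encodings
  raise an explicit unsupported-dialect error rather than misparse).
* The numpy neural networks are small-scale research implementations; they
  are not performance-competitive with GPU frameworks and intentionally
  favour auditability.
* The automatic ICA artifact rule is a heuristic stand-in for expert visual
  component review.
* Holdout/k-fold pool all events; per-subject (leave-one-subject-out)
  evaluation is out of scope, as is feature selection.
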