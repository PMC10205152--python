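# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic validation shows.

## Encoding model

Each EEG channel is modelled as a linear time-invariant response to a set of
named predictor variables:

    y_c(t) = Σ_i Σ_d (h_{i,d,c} ⊛ x_{i,d})(t) + ε_c(t)

where predictor *i* has dimensions *d* (e.g., 8 spectrogram bands), and each
kernel h spans lags −100…500 ms relative to the stimulus.  Kernels are
parameterised in a basis of 50 ms Hamming windows with one coefficient per
lag sample (10 ms at the 100 Hz EEG rate); windows are truncated at the ends
of the lag axis.  The basis makes estimates smooth at the 50 ms scale and is
linear, so kernel expansion commutes with averaging across fits.

Convolution is computed independently per trial: predictors are zero-padded
at trial boundaries and no sample of one trial influences another.

## Boosting estimator

Coefficients are estimated by greedy coordinate descent on the training-set
ℓ1 prediction error.  At each step, the single update — one coefficient of
one predictor dimension moved by a fixed increment δ in either direction —
that most reduces the training error is applied; the validation-set ℓ1 error
is then evaluated, and if it increased, the update is reverted and the named
predictor responsible is frozen in its prior state for the remainder of the
fit.  Estimation ends when all predictors are frozen, when no update can
reduce the training error, or at `max_steps`.

Numerical choices:

* **Step size.**  δ = `step_frac` × SD of the training response, default
  `step_frac = 0.005`.  Predictor dimensions are rescaled to unit mean
  absolute value before fitting so that δ is comparable across dimensions;
  kernels are rescaled back to original response/predictor units for
  reporting.  The response is mean-centred per channel over the training
  samples; predictors are not centred, so the design matrix can be built
  once and shared across all cross-validation fits.
* **Exact argmax.**  For residual r and candidate update u, the ℓ1 change
  decomposes as −Σ sign(r)·u plus a nonnegative correction supported only on
  samples with |r(t)| < δ·max_j |c_j(t)|.  The first term is one
  matrix-vector product over all candidates; candidates that could win are
  then evaluated exactly on the correction support.  The applied update is
  the exact argmax; ties break to the lowest (predictor, basis index).
* **Freezing granularity.**  All dimensions of one named predictor freeze
  together (the unit the validation step blames); `freeze="dimension"`
  freezes single dimensions instead.
* **Degenerate inputs.**  A zero-variance channel or predictor dimension is
  a fit error naming the offender; |r| = 1 in the Fisher transform maps to a
  configurable cap (default ±15) with a warning.

## Cross-validation and accuracy

Trials are split into 5 test folds of near-equal size.  For each test fold,
the remaining 4 folds rotate through the validation role, giving 4 models;
the test fold is predicted from the average of their coefficients (by
linearity this equals the average of their predictions).  Accuracy per
channel is the Pearson correlation between the concatenated test-fold
predictions and the measured response (both mean-centred over the
concatenation), Fisher z-transformed.  Because no model ever sees its test
fold, an uninformative predictor has expected z = 0 — the chance-level
suite (50 pure-noise simulations × 8 channels) measures this directly.  One
caveat the suite makes visible: computing a *single* r over the
concatenation of all test folds carries a tiny negative finite-sample bias
(order 10⁻³ in z at these problem sizes), because models fitted on one fold
overfit that fold's data, which couples the concatenation-level
normalisation with every other fold's contribution.  Per-fold correlations
do not show this bias; the concatenated statistic is nevertheless what the
estimator reports, as the single-accuracy-per-model convention requires.

Unique predictive power of a predictor set is Δz = z(full) − z(reduced),
computed with the same folds on the same data.  The reported TRF is the
average over all 20 fitted models.  Visual onset and offset TRFs are
combined into one effective response function by shifting the offset kernel
by the 500 ms stimulus duration and summing on the overlap, yielding a
−100…1000 ms axis.

## Inference

Cluster-mass permutation tests: per-point t values (one-sample, or paired
via differences) are thresholded at the t equivalent to uncorrected p ≤ 0.05
(one- or two-sided); suprathreshold points are clustered by adjacency
(explicit neighbour lists; Delaunay-with-distance-threshold construction
from montage coordinates; chain adjacency for time axes); each cluster's
mass (sum of t) is compared against the null distribution of the maximum
cluster mass under whole-subject sign flips.  When 2^n ≤ 10 000 the full
flip set is enumerated, making the test exact, deterministic and
seed-independent; the identity flip is always a member, so p > 0.  The
observed t statistics are taken from the identity row of the same vectorised
computation as the null rows, so this guarantee holds bit-exactly.  `t_max`
(largest |t| in a cluster) is reported as an effect-size proxy.  GFP is the
across-channel population standard deviation at each lag.

## Synthetic data

The generators emulate the study conditions rather than any recorded
dataset:

* **Trial structure** defaults to 15 trials of 60 s per condition, EEG at
  100 Hz, epochs capped at 61 s, predictors on a 1 kHz grid decimated by the
  shared resampler (anti-aliased for dense series; value-preserving
  re-binning for impulses).
* **n-back sequences**: 23 squares of 500 ms at 8 loci with 2.5 s ISI
  (69 s trials); 6 targets placed among the last 20 items; the 3-back/0-back
  rule holds at targets and fails at all other applicable positions.
* **Language material**: random pronunciation lexicons over a small phoneme
  inventory with Zipf-distributed token frequencies (exponent 1 by
  default); timelines place phonemes at 8/s with ±10% interval jitter, a
  rate typical of running speech.
* **EEG**: per-trial convolution of known kernels with the predictors plus
  i.i.d. Gaussian noise (the minimal testable noise model; the noise
  spectrum and amplitude of real EEG are free parameters here, so SNR is a
  simulation knob, 10 dB by default, not a matched quantity).  The object
  exposes signal and noise parts whose sum is bit-identical to the data.

What passing synthetic tests does *not* show: robustness to non-Gaussian,
autocorrelated EEG noise, artifacts, forced-alignment errors, or the strong
temporal correlations between real speech predictors.  The Δz logic
specifically is validated only under predictors with modest mutual
correlation.

## Validation problem sizes

The heavier suites run at sizes chosen to exercise the contracts with
comfortable statistical margins: chance level uses 50 simulations of
10 × 30 s trials at 8 channels; parameter recovery and Δz attribution use
200 s at SNR 10 dB with 4 channels (kernel recovery threshold r ≥ 0.8;
observed ≈ 0.99); the oracle-equivalence check compares boosting on
noiseless data against the λ→0 ridge solution (lag-wise r ≥ 0.99, achieved
with a white-noise predictor — with strongly autocorrelated predictors the
greedy ℓ1 path and the ℓ2 solution legitimately differ); cluster-test
calibration uses 500 null datasets of 10 subjects × 16 channels with the
exact 1024-flip enumeration.

## Design notes

* The auditory edge detector is specified here as rectified delayed
  inhibition, o(t) = max(0, x(t) − c·x̄(t−d)) with x̄ a 10 ms causal moving
  average, d = 10 ms, c = 1: zero on constants, rectified transients on
  increments.  A numerical floor (10⁻⁹ of the input scale) keeps running-sum
  round-off from registering as onsets.
* Gammatone filters are 4th-order cascades of four biquads with shared
  resonator poles and standard zero placements, gain-normalised at the
  center frequency — stable at low center frequencies where a flattened
  8th-order transfer function is not.  Center frequencies are ERB-rate
  spaced over 20 Hz–5 kHz; the 8-band summation groups are defined by
  log-spaced frequency edges.  Compression is log(1 + x); summation after
  compression by default, with a pre-compression mode in which the 8-band
  sum conserves total energy exactly.
* N-gram smoothing is interpolated Kneser–Ney (discount 0.75, final
  interpolation with the uniform distribution) for realistic use, and exact
  unsmoothed relative frequencies for oracle testing.  Homophones are
  separate lexicon entries splitting the word's count mass; missing words
  get count 1.  Sentence-model priors use exactly the 4 preceding words,
  resetting at utterance boundaries; cohort die-off (a phoneme matching no
  lexicon entry) either raises or falls back to uniform scoring over the
  inventory, per configuration.
* Impulse gridding: an event at time t lands on sample floor(t·fs);
  same-sample events sum.
* Pipeline artifacts carry manifests (content hashes of inputs, outputs,
  config, seed — no timestamps), so reruns are bit-identical and tampered
  inputs are refused.
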