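# Methods

This note records the models, defaults and design decisions behind
`drowsyeeg`, and what the synthetic-data experiments do and do not
establish.

## Problem setting

A portable single-channel EEG (Fp1 referenced to A1, 512 Hz, dry
electrodes) records 60 s resting traces; after each recording the wearer
reports a Karolinska Sleepiness Scale rating (1–9). The task is binary:
classify 10 s windows as *alert* or *drowsy*, where the classes are
defined by strict KSS thresholds, and aggregate window decisions into a
per-recording drowsiness probability. Prefrontal single-channel EEG only
weakly reflects sleepiness, so the realistic accuracy regime is ~65–75%,
not the >90% reported for multichannel driver-monitoring systems.

## Synthetic data generator

No public dataset exists for this recording setup, so `synth` generates
cohorts with the statistical structure the pipeline assumes:

* **Signal model.** Each recording is a sum of band-limited Gaussian
  noise components (white noise through zero-phase 4th-order Butterworth
  band-passes, rescaled to a target variance), a 50 Hz mains sinusoid,
  and Poisson eye-blink transients (smooth biphasic pulses, ≈0.5 s,
  spectral energy below 8 Hz, amplitude ≈60 µV).
* **Drowsiness encoding.** Band variance is
  `baseline + effect_size · slope · latent`, with latent drowsiness in
  [0, 1]. Defaults (µV²): delta 20 + 4·latent, theta 10 + 10·latent, alpha
  (8–10 and 10–12) 5 + 6·latent each, sigma 4 + 2·latent; beta/gamma/high
  bands carry no drowsiness signal. This encodes the classical finding
  that theta and alpha power rise with sleepiness, with a weaker delta
  trend. `effect_size` (default 1) scales all slopes; 0 removes the class
  signal entirely. The literature does not quantify the alert→drowsy power
  shift for this montage, so the default slope magnitudes are a package
  choice: they give roughly a doubling of theta power from fully alert to
  fully drowsy, which produces clearly learnable but not trivial classes.
* **KSS model.** Latent drowsiness maps to KSS through 8 equally spaced
  thresholds at j/9 plus logistic noise (scale 0.05): an ordinal probit-like
  response with latent 0 → KSS 1 and latent 1 → KSS ≥ 7 with high
  probability. Sessions cycle morning → daytime → night; latent values
  draw from session-specific Beta distributions (morning Beta(4,2), daytime
  Beta(1.8,2.2), night Beta(5,1.5)) so wake-up and bedtime recordings are
  drowsier, daytime mixed.
* **Determinism.** Every draw flows from `numpy.random.default_rng(seed)`;
  identical configs give bit-identical signals and manifests.

**What the generator does not emulate:** 1/f background structure,
non-stationarity within a recording, electrode-contact artifacts and
impedance drift, EMG broadband bursts, subject-specific spectral
signatures, or any nonlinear dynamics (the band-limited-Gaussian model has
no complexity structure for MSE to exploit; MSE features are exercised for
correctness, not for synthetic classification power). Passing tests
therefore show the *pipeline machinery* is correct and leak-free — not
that real dry-electrode data reaches any particular accuracy.

## Preprocessing

Wavelet: db4 (a standard choice for EEG denoising; the family is
configurable), 6 decomposition levels, symmetric padding. Soft threshold
λ = σ√(2 ln N) with σ = MAD(finest detail)/0.6745 (the universal rule);
a fixed-λ mode exists, and λ = 0 reproduces the input to ≤1e−8 relative
error (perfect reconstruction).

Artifact removal zeroes coefficients with |c| > k·(1.4826·MAD) at the
configured detail levels (k = 3 default). Level numbering is a real
ambiguity: by the conventional fine-end indexing used here, level k covers
fs/2^(k+1)–fs/2^k Hz, so at 512 Hz the default levels (2, 4) are the
64–128 Hz and 16–32 Hz bands — useful against EMG, nearly inert against
smooth sub-8 Hz blinks. Under coarse-end numbering with 6 levels, levels
(2, 4) are 8–16 Hz and 32–64 Hz, which matches the classical blink/EMG
artifact frequencies; `level_indexing="coarse"` selects that convention.
To actually remove blinks, set artifact levels covering 1–8 Hz (e.g.
`n_levels=8, artifact_levels=(6, 7, 8)` under fine indexing) — the blink
test in the suite does exactly this. Note the device already applies a
50 Hz notch in hardware; the denoiser only reduces residual mains power.

## Features

* **Band power**: single Blackman-tapered periodogram per 10 s window
  (no Welch sub-segmentation by default — Welch is config-gated), power =
  rectangle-rule integral of the PSD over half-open [low, high) bins.
  Absolute linear power is used (no log transform, no relative power);
  both alternatives are easy to add upstream of the scaler, and the robust
  scaler absorbs monotone scale differences. One numerical consequence of
  the taper: a tone at exactly a band edge (e.g. 10 Hz) leaks ±3 bins of
  mainlobe symmetrically, so ~21% of its energy lands in the band below;
  only tones ≥0.3 Hz interior to a band concentrate ≥95% of their power
  in it at 0.1 Hz resolution.
* **AR(5)**: biased sample autocovariances, Yule–Walker system solved by
  Levinson-type Toeplitz solve; sign convention
  x_t = a₁x_{t−1} + … + a₅x_{t−5} + e_t. Constant input raises a
  singularity error rather than returning NaNs.
* **MSE**: coarse-grain by non-overlapping τ-block means, SampEn with
  m = 2 and r = 0.15·SD of the *original* (scale-1) window held fixed
  across scales (the standard definition; per-scale r is config-gated).
  n_scales defaults to 20 and the coarsest scale must retain ≥10·(m+1)
  points. SampEn counts template pairs over the first N−m embeddings at
  both lengths (the Richman–Moorman convention) using a KD-tree with
  Chebyshev metric; `A = 0` or zero variance yields NaN (undefined),
  never 0.

## SWLDA

Stepwise OLS on the 0/1 label, the standard BCI formulation: forward step
adds the candidate with the smallest partial-F p-value if p < p_enter
(0.1); backward steps remove any included feature with partial-F
p > p_remove (0.15). The F statistic is ΔRSS/(RSS_full/dof) against
F(1, n − k − 2). Determinism: candidates are scanned and ties broken in
lexical feature-name order, making results row-order invariant.
Termination: no-change pass, repeated model state (cycle guard), or
max_steps (default 2·n_features). Numerically collinear candidates
(no measurable RSS improvement at rank deficiency) get p = 1 and are
skipped — with duplicated features exactly one of the pair survives.
Null calibration: with 10 pure-noise features and random labels the
procedure admits ≈1 feature on average (≈ p_enter · n_features), per-noise
feature ≈0.10.

Selection runs *per outer CV fold* by default (inside
`DrowsinessClassifier.fit`), so held-out windows never influence the
selected set; a global pre-selection mode is available through the
`select` CLI command for workflow replication, at the cost of optimistic
bias.

## Robust scaling

z = (x − median)/NIQR with NIQR = (q₆₅ − q₃₅)·0.7413, quantiles by linear
interpolation of order statistics (numpy default, "type 7" — this matters
on small samples). 0.7413 is the normal-consistency constant for the
25–75 IQR; with the 35/65 pair the consistent constant would be
1/(2·Φ⁻¹(0.65)) ≈ 1.293. The 0.7413 constant is kept as the primary
definition because the 35/65 quantile pair with that constant is the
scaler this system is defined with (it only rescales all features by a
common factor, which the RBF-SVM's γ search absorbs);
`consistent_constant=True` switches to the normality-consistent factor.
Features with zero quantile spread on the training rows are flagged and
dropped with a warning. The scaler is always fitted on training rows only
and serializes to JSON for reuse at inference time.

## Classification and evaluation

RBF-SVM (scikit-learn SVC). Grid: C ∈ 2⁻²…2¹¹, γ ∈ 2⁻¹⁰…2³, exponent
step 1 (196 points); `GridSpec.coarse(step)` thins both axes for cheaper
runs. Inner model selection is stratified k-fold (default 10, shuffled,
seeded) maximizing accuracy; ties break to the smallest C, then smallest
γ. Outer evaluation is stratified 10-fold at the window level by default —
this replicates the development analysis, but windows of one recording are
not independent, so a recording-grouped outer mode (`groups=`) and
leave-one-subject-out CV are provided; LOSOCV is the honest estimate of
subject-level generalization, and the suite includes a fixture where a
subject-confounded feature inflates window-wise CV while LOSOCV stays at
chance.

Metrics: precision, sensitivity, specificity, accuracy, F-measure in
percent from pooled outer-fold confusion counts (positive class =
drowsy); zero-denominator metrics are NaN/null, never 0. ROC from pooled
decision scores, AUC by trapezoid (equal to the pairwise ranking
probability, tested exhaustively). Drowsiness probability = mean of a
recording's binary window outputs. Condition comparison = paired t-test
on per-subject probabilities (each subject does both tasks); identical
paired samples return t = 0, p = 1 by convention rather than NaN, and an
unpaired mode exists.

## Problem sizes used in checks

The automated checks run the full pipeline at the default cohort size
(29 subjects × 15 recordings, 2610 windows) with a thinned grid (exponent
step 2 for nested CV, step 4 for LOSOCV), and property suites at the sizes
stated in their docstrings (e.g. 100 seeds × ≤200-point windows for the
sample-entropy oracle, n = 30720 for AR recovery). The practical
experiment uses 20 task subjects × two 300 s recordings with training on a
10–12 subject cohort. These sizes are the package's own balance between
statistical resolution and a few minutes of single-CPU runtime.

## Known limitations

* Synthetic data is linear-Gaussian per band; MSE and AR features add no
  discriminative value on it even though both are computed correctly.
* The exclusion bookkeeping of real studies (missing KSS, corrupted
  recordings) is represented only by the `excluded` label path.
* Window-level CV overestimates deployment accuracy whenever windows of a
  recording share state; prefer LOSOCV numbers.
* The EDF reader handles single-channel files only (by design); the
  vendor's proprietary stream format is out of scope, as are live
  acquisition and multichannel montages.
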