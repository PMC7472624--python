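# Methods

This note documents the models, numerical choices and limitations of
the `eegspeech` pipeline, in the order data flows through it.

## Synthetic EEG generator (`eegspeech.synthetic`)

The generator emulates the statistical structure a small imagined-speech
EEG study presents to a decoder, not the physiology that produces it.

**Background.**  Each trial and channel is independent Gaussian noise
synthesized in the frequency domain with amplitude ∝ f^(−α/2)
(default α = 1), multiplied by the squared frequency response of the
same 2–40 Hz windowed-sinc FIR the preprocessing stage uses, and
normalized to unit SD.  Because the synthesis is circular, multiplying
by |H(f)|² is exactly the forward–backward application of that filter.
The band-limiting mirrors recordings that are distributed already
band-passed; a log–log periodogram fit between 3 and 35 Hz recovers the
configured exponent to within a few percent (tested at ±20 %).

**Class signal.**  Each class receives narrow-band Gaussian bursts in
one canonical band with a class-specific channel emphasis pattern
(two emphasized channels at weight 1, the rest at 0.3).  Burst RMS is
`snr × multiplier × subject jitter` in units of the background SD, so
`snr = 0` makes labels exactly independent of the data — the basis of
all chance-calibration checks.  By default the class bands cycle
through theta…gamma and deliberately exclude delta (2–4 Hz), so the
class-signal subspace stays separable from the low-frequency blink
artefact; with six channels carrying roughly a dozen latent sources,
letting a class share the blink band makes ICA-based artefact isolation
unreliable.

**Subject variability.**  A per-subject log-normal global gain and
per-class log-normal jitter on effect sizes (both SD 0.2 in log space).
This is what makes intra- vs inter-subject hyperparameter selection a
meaningful comparison on synthetic data.

**Blinks.**  A 300 ms biphasic, Hann-windowed waveform with
frontal-dominant topography (F = 1.0, C = 0.35, P = 0.1 of the peak),
injected at Poisson-distributed counts per trial (default expectation
2) with peak amplitude 7 × the background SD on frontal channels and
±20 % uniform amplitude jitter.  The amplitude was set so that a
six-channel FastICA isolates the blink component reliably enough for
the 0.8 template-correlation screen to fire across generator seeds; at
5 × SD the screen missed the component in roughly half of the seeds
once class bursts compete for the six available components.  Units
throughout are arbitrary (background SD ≈ 1); no microvolt calibration
is claimed.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real recordings: cortical source geometry and
volume conduction (channel correlations arise only through blink and
burst topographies), non-stationarity within sessions, EMG/line noise,
overt-speech trials, and realistic class-discriminative structure of
imagined speech, which is unknown; the class effects here are
stipulated band-power signatures, chosen because band power is what
every decoder in the pipeline targets.  Results on synthetic data
validate the *machinery* (no leakage, correct selection, chance
calibration), not achievable real-data accuracy.

## Preprocessing (`eegspeech.preprocess`)

* **Band-pass**: windowed-sinc (Hamming) FIR, odd length, default order
  3·fs/f_lo (≈1537 taps at 1024 Hz for a 2 Hz edge).  Applied
  forward–backward, each pass an FFT convolution in `same` mode after
  odd (anti-symmetric) edge extension, i.e. zero phase with |H|²
  magnitude.  This form handles 1500-tap kernels on 4096-sample trials
  where a direct-form forward–backward filter would violate its padding
  constraint and cost ~100× more.
* **Resampling**: `scipy.signal.resample_poly` (polyphase with its
  Kaiser anti-aliasing filter); 1024 → 128 Hz turns a 4 s trial into
  512 samples.
* **ICA blink screening**: FastICA (tol 1e-4, max 500 iterations,
  seeded) fitted per subject on the concatenated trials decimated by 3
  (spatial unmixing is rate-independent; decimation only speeds up the
  fit), then applied to the full-rate concatenation.  Component maps
  (mixing columns) are Pearson-correlated with a blink-topography
  template; components with |r| ≥ 0.8 are flagged.  Absolute
  correlation is used because ICA component signs are arbitrary.
  Removal zeroes flagged sources and remixes.  A config-level
  `override_keep` list substitutes for interactive visual inspection.
  If a previous removal left the data rank-deficient, the component
  count defaults to the covariance rank, which is what makes
  screen+remove idempotent.

## Features (`eegspeech.features`)

* **RWE**: 5-level db4 DWT with symmetric padding at 128 Hz.  Energies
  of D2–D5 and A5 (sums of squared coefficients) are normalized per
  channel by their sum; the nominal D1 level (32–64 Hz) is computed and
  discarded.  The 6-channel, 5-level layout yields 30 features ordered
  channel-major.
* **Filter bank**: the six canonical bands, same FIR family as
  preprocessing with order 3·fs/f_lo per band, capped so two passes fit
  a 512-sample trial.
* **CSP**: per band, per-trial covariances (computed once per dataset —
  they are label-free) are averaged per class.  Two classes: the
  generalized eigendecomposition of (Σ₁, Σ₁+Σ₂), nSF eigenvectors from
  each end; the eigenvector normalization makes Wᵀ(Σ₁+Σ₂)W = I on the
  training data.  More classes: one-vs-rest per class, each class
  contributing its nSF largest-eigenvalue filters, the pooled set
  capped at 2·nSF per band by eigenvalue extremity |λ − ½| (ties by
  class then rank).  Singular covariances get an escalating ridge
  (10⁻¹⁰ … 10⁻³ of the mean diagonal) with a warning; if still singular
  the fit raises and the grid-search layer records accuracy 0.
* **Selection**: candidate features are log-variances of all CSP
  projections (6 bands × 2·nSF).  Mutual information against labels is
  the plug-in estimate on MIQL equal-frequency (rank-based) bins; the
  top NoF features are kept, ties broken by feature index.  The plug-in
  estimator is positively biased at finite n — tests therefore compare
  a null feature's MI against a permutation-null distribution rather
  than against zero.  The MIQL grid defaults to (6, 8, 10, 12); an
  alternative (2, 4, 6, 8) is accepted through configuration, since
  either quantization range is defensible.

## Decoders (`eegspeech.decoders`, `eegspeech.nn`)

The three CNNs run on a compact numpy layer stack (grouped stride-1
convolution via im2col, batch norm, mean/max time-pooling, dropout 0.5,
dense; hand-derived backward passes; ADAM).  Every layer's gradient is
checked against central finite differences in the test suite.  Kernel
sizes and filter counts follow the original architecture publications,
scaled to 6 channels × 512 samples:

* **shallow**: 40 temporal filters (1×25) → 40 spatial filters (6×1) →
  batch norm → activation (default square) → mean-pool 75/stride 15 →
  log (clamped at 10⁻⁶) → dropout → dense softmax.
* **deep**: initial temporal (25×(1×10)) + spatial block, then three
  identical blocks [dropout, conv (1×10) at 50/100/200 filters, batch
  norm, activation, max-pool 3] → dense softmax.
* **EEGNet**: 8 temporal filters (1×64, same padding) → depthwise
  spatial (6×1, depth 2) → BN/activation/mean-pool 4/dropout →
  separable conv (depthwise 1×16 + pointwise) → BN/activation/
  mean-pool 8/dropout → dense softmax.

Trainable parameter counts at 6×512/6 classes: EEGNet 2 742 <
shallow 17 446 < deep 268 831.  The activation hyperparameter replaces
the principal nonlinearity in all three networks (including both
EEGNet blocks); leaky ReLU uses slope 0.01; the square activation pairs
with the clamped log stage.  Inputs are z-scored per trial and channel
before the CNNs.  EEGNet's original max-norm weight constraints are not
implemented.  Training: ADAM, batch 64, the grid's learning rate and
epoch count, loss either mean NLL of the true class or the summed
per-class binary cross-entropy averaged over trials (the two losses
agree at 0 exactly for one-hot-correct predictions).  A non-finite loss
or parameter raises a divergence error, which the grid search absorbs
as accuracy 0 so the enumeration stays total; in practice batch norm
plus the clamped losses keep even lr = 1.0 finite, and "divergence"
manifests as chance-level accuracy instead.

Classical baselines: SVC and RandomForestClassifier (scikit-learn) on
RWE vectors, and for FBCSP a package-local shrinkage LDA (pooled
within-class covariance shrunk toward scaled identity with the analytic
Ledoit–Wolf intensity, softmax probabilities).  The local
implementation exists because nested CV fits the LDA thousands of times
per subject and the library implementation spends ~99 % of that time in
input validation; it is cross-checked against scikit-learn's
`LinearDiscriminantAnalysis(solver="lsqr")` exactly at fixed shrinkage
and at the prediction level for the analytic intensity.

## Nested CV (`eegspeech.nested_cv`)

Stratified outer k-folds (k = 4: 75 %/25 % train/test); for each outer
fold the k−1 training folds are re-partitioned into k stratified inner
folds (75 %/25 % train/validation), re-seeded deterministically from
(outer index, master seed).  One validation accuracy per (θ, outer,
inner); θ* is the argmax of the mean over all k×k inner evaluations,
ties to the earliest enumerated combination.  Inner k equals outer k.
The full inner table is retained on every result object so per-value
marginal means can be recomputed.  Fold hygiene: per-trial band
covariances and RWE vectors are precomputed once (label-free), but CSP
filters, MI ranking and all model fits happen strictly inside training
splits; a dedicated test permutes held-out trials and asserts bit-equal
inner tables.  Inter-subject mode averages each θ's mean validation
accuracy across subjects before the argmax; every subject is then
evaluated with the shared θ*.

Per-class precision TP/(TP+FP) is pooled over outer folds; classes
never predicted are recorded as absent and excluded from the macro
mean.

## Statistics (`eegspeech.stats`)

One-factor repeated-measures ANOVA (statsmodels `AnovaRM`) for
per-hyperparameter effects within subjects; two-way ANOVA with
interaction (OLS + type-II table) for hyperparameter × decoder
questions; Tukey HSD for post-hoc pairs; α = 0.05.  Accuracies enter
untransformed (percent scale).  Degenerate inputs are made explicit:
a table with no between-level variation reports F = 0, p = 1, and
zero-pooled-variance Tukey comparisons report p = 1 for identical
groups.  Both ANOVAs are verified against hand-computed sums of squares
to 1e-8 on random balanced tables, and the two-way interaction's type-I
error is simulation-checked at 5 %.

## Problem sizes used by tests and the acceptance script

Chance calibration runs 3 subjects × 20 trials/class × 10 seeds per
task with the full 64-point FBCSP-rLDA grid — about 3 600 (words) and
3 000 (vowels) outer-fold test trials per estimate, giving a 3-SD
binomial band of roughly ±1.9 and ±2.2 percentage points around the
16.67 % and 20 % chance rates.  CNN learning checks use a 2-class,
200-trial dataset at snr = 2 with 8–20 epochs; these sizes demonstrate
above-chance learning and determinism, not converged accuracy.  The
full 15-subject, 6-family, two-mode study design is encoded in
`configs/paper_words.yaml` / `configs/paper_vowels.yaml` and runs the
same code paths unchanged.

## Known limitations

* The numpy CNN engine is single-threaded and CPU-bound; full 128-point
  CNN grids at 15 subjects are a long-running batch job, not a desk run.
* SVC probability estimates use Platt scaling with internal CV
  (scikit-learn), adding noise at very small fold sizes.
* The blink screen depends on ICA finding the blink component; with six
  channels and many competing sources, detection is reliable at the
  default artefact strength but degrades for weaker/rarer blinks.
* Multi-class CSP by one-vs-rest with an extremity cap is one of
  several defensible schemes; with the cap at 2·nSF per band some
  classes may contribute no filters in a given band.
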