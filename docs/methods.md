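# Methods

## Problem and pipeline

`semgrasp` classifies hand grasps (cylindrical CY, tip TI, hook HO,
palmar PA, spherical SP, lateral LA) from 2-channel surface EMG of the
forearm flexor/extensor muscles, sampled at 500 Hz. The pipeline is:

1. **Segmentation** — each labelled trial is cut into sliding windows of
   2000 samples (4 s) at an 80-sample hop (0.16 s). Windows inherit the
   trial's label; a 6-s trial yields `floor((3000-2000)/80)+1 = 13`
   windows. Indexing is 0-based and half-open; trailing samples that do
   not fill a window are dropped (padding would fabricate signal), and
   windows never cross trial boundaries.
2. **Variational mode decomposition (VMD)** — each window channel is
   decomposed into K narrowband modes (VMFs) plus a residual.
3. **Features** — MAV, MDF, MNF and permutation entropy per component;
   with 2 channels, K = 10 and the residual, the window's feature vector
   has 2 x 11 x 4 = 88 entries.
4. **ReliefF** — multiclass feature weighting; the top-42 subspace is
   the shipped default. A per-feature Kruskal-Wallis screen checks that
   retained features differ across classes.
5. **Classification** — quadratic discriminant analysis, degree-2
   polynomial SVM, or bagged decision trees, scored by stratified
   10-fold cross-validation per subject with per-class
   accuracy/precision/recall/F1 from the pooled confusion matrix.

## VMD

VMD solves, by ADMM in the frequency domain, for K modes u_k with
centre frequencies w_k minimising the summed bandwidth of the
demodulated modes subject to (soft) reconstruction. Updates per sweep:

    u_k <- (f - sum_{i != k} u_i + lambda/2) / (1 + 2 alpha (w - w_k)^2)
    w_k <- int w |u_k|^2 dw / int |u_k|^2 dw   over w >= 0
    lambda <- lambda + tau (f - sum u_k)

stopping when `sum_k ||u_k^{n+1} - u_k^n||^2 / ||u_k^n||^2 < tol`.

Defaults: `alpha = 2000` (bandwidth penalty; larger = narrower modes),
`tau = 0` (no exact-reconstruction dual, robust to broadband noise),
`tol = 1e-7`, `max_iter = 500`, uniform initialisation with centres at
the band midpoints `(k + 1/2)/K` of `[0, Nyquist]` — no dedicated DC
mode, since physiological sEMG is high-passed at 15 Hz. All are exposed
in `VmdConfig`. Numerical choices:

* the signal is mirror-extended by half its length on each side before
  the spectral iteration and cropped after, reducing edge artefacts;
* the one-sided spectrum (rfft) carries the iteration; modes return to
  the time domain by inverse rfft (Hermitian symmetry);
* the residual is defined as `input - sum(modes)`, so additive
  reconstruction is exact by construction at machine precision;
* modes are reordered by ascending centre frequency after convergence so
  that feature positions are comparable across windows;
* non-convergence within `max_iter` is reported via `converged=False`
  and a log message, never an exception — on broadband noise with
  K = 10 the iteration commonly uses the full budget while the modes are
  already stable to ~1e-6;
* the ADMM inner loop is a numba kernel; batched calls iterate each
  signal to its own stopping point, so batch and single-signal results
  are bit-identical.

## Features

* **MAV** `= (1/N) sum |x_i|` — amplitude scale (degree-1 homogeneous).
* **Spectrum** — one-sided boxcar periodogram scaled to power, so total
  power equals the mean square (Parseval). No taper or averaging: the
  components are narrowband, and the estimator is pluggable.
* **MDF** — discrete bins rarely split power exactly in half, so MDF is
  the frequency of the smallest bin index whose cumulative power reaches
  half the total (deterministic tie rule).
* **MNF** `= sum f_j P_j / sum P_j`.
* **PeEn** — ordinal patterns of the `(m, delay)` embedding with
  `m = 3, delay = 1` by default (the shortest standard embedding; both
  configurable), probabilities by relative frequency, entropy in nats
  (bounded by `ln m!`). Ties inside an embedding vector are broken by
  order of occurrence (stable ranking), keeping the statistic
  deterministic.
* Components with zero spectral power (e.g. an exactly zero residual)
  get MDF = MNF = 0 with a logged warning rather than aborting a batch.

## ReliefF

Kononenko's multiclass form: for each sampled instance, k nearest hits
and per-class k nearest misses by Manhattan distance on range-normalised
features (neighbours found in the full feature space; the per-feature
`diff` drives the update), miss contributions weighted by
`P(C)/(1 - P(class(R)))`. Defaults `k_neighbors = 10` and a
deterministic pass over all instances (`m_samples="all"`), which removes
sampling noise; random subsampling with a seed is available. Constant
features score exactly 0; weights lie in [-1, 1]. Because neighbour
search uses the full feature space, adding or removing a feature can
perturb the other features' weights slightly — rankings of clearly
informative vs. noise features are stable, exact values are not meant
to be.

## Classifiers

"Discriminant with a quadratic boundary" is implemented as quadratic
discriminant analysis (`lda_quadratic`), with plain LDA available; a
singular class covariance triggers a regularised refit
(`reg_param = 1e-3`) with a warning. The SVM uses the kernel
`(x.y/d + 1)^2` (d = feature count, i.e. scikit-learn `gamma="auto"`,
`coef0=1`), C = 1, one-vs-one multiclass. Bagging uses 100 unlimited-
depth trees with bootstrap resampling under the run's seed. Features are
standardised with training-fold statistics only (units are mixed: mV,
Hz, nats). Cross-validation is stratified at the window level within a
subject — windows of one trial may land in different folds, which
mirrors the per-window protocol; a trial-grouped mode (`groups=`)
is provided for leakage-free evaluation.

## Experiments

* **Mode-count sweep** — full pipeline per K (no feature selection, no
  mode reuse across K: correctness over speed), mean CV accuracy per
  subject per K. The per-K feature space is `channels x (K+1) x 4`.
* **Dimension sweep** — one ReliefF ranking computed on the full table
  and reused for every d, so d = 88 reproduces the no-selection run
  exactly; dims reported ascending.
* **Noise robustness** — additive zero-mean Gaussian white noise with
  std = level x per-channel signal std (the level is unitless relative
  noise; 0.6 means 60 % of the signal's std). Default protocol perturbs
  all recordings and re-runs the standard pipeline + CV; a
  train-clean/test-noisy mode is also provided.

## Synthetic data

The generator emulates the acquisition geometry: 6 classes x 30 trials
x 6 s at 500 Hz, 2 channels. Class c is Gaussian noise band-passed to
its own 20-Hz-wide band (30-50, 60-80, ..., 180-200 Hz — all inside the
15-245 Hz range that survives the real preprocessing), multiplied by a
contraction envelope with c+1 smooth bursts, mixed onto the channels
with class-dependent gains, plus a 5 % white-noise floor. Band
separation makes the classes cleanly separable by spectral features:
this is intentional, so end-to-end thresholds are stable across
platforms. What the generator does **not** model: motor-unit action
potential trains, inter-trial electrode shift, fatigue-induced spectral
compression, cross-talk, class overlap. Passing end-to-end tests
therefore demonstrates that the machinery is correct and the feature
chain preserves class information — not that real sEMG reaches the same
accuracy.

## Problem sizes used by tests and the acceptance script

The full-protocol run uses the generator defaults (1 subject, 180
trials, 2340 windows, K = 10, 88 features, top-42, 10-fold SVM). The
sweep-machinery checks run on 6 classes x 2 trials with a 250-sample
window hop (10 windows per class), chosen so every protocol still
satisfies its structural invariants (table shape, determinism, ordering)
at desk scale. The Kruskal-Wallis calibration uses 6 groups x 50
samples x 1000 null replicates, where the chi-squared approximation to
the H statistic is accurate.

## Known limitations

* VMD mode count K must be chosen; the sweep protocol is the supported
  way to pick it (no automatic K estimation).
* The periodogram is a high-variance spectral estimator; MDF/MNF inherit
  that variance at the window level (averaging estimators can be
  substituted via `estimate_spectrum`).
* ReliefF is O(n^2) in the number of windows per subject (pairwise
  distances); ~2500 windows is comfortable, 10x that is not.
* The UCI reader pairs the two channels' trial matrices by row index;
  the source format does not state the pairing explicitly.
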