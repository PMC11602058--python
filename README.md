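# semgrasp

Surface-EMG grasp recognition by variational mode decomposition,
four-feature extraction, ReliefF selection and classical classifiers.

## The problem

Forearm surface EMG (sEMG) carries the motor intent behind hand
movements, which makes it the input of choice for prosthetic control
and rehabilitation training. The difficulty is that the activity of
many muscles overlaps in one skin-surface recording; classifying a
grasp reliably requires first separating the signal into narrowband
components and then keeping only the features that actually
discriminate between grasps. `semgrasp` implements that pipeline for
2-channel recordings of six grasp types — cylindrical (CY), tip (TI),
hook (HO), palmar (PA), spherical (SP), lateral (LA) — sampled at
500 Hz.

## The method

For each labelled trial, sliding windows of 2000 samples (hop 80) are
decomposed per channel by **variational mode decomposition (VMD)**: K
narrowband modes u_k with centre frequencies ω_k are obtained by ADMM,
alternating a Wiener-like spectral update

    û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²)

with the spectral centre-of-gravity update for ω_k, plus a residual
defined as the input minus the mode sum. Each of the K modes and the
residual contributes four features:

* MAV = (1/N) Σ|x_i| — mean absolute value,
* MDF — the frequency splitting the power spectrum into equal halves,
* MNF = Σ f_j P_j / Σ P_j — power-weighted mean frequency,
* PeEn = −Σ P_j ln P_j over ordinal-pattern probabilities — permutation
  entropy (m = 3, delay = 1).

With 2 channels and K = 10 this yields an 88-dimensional feature space,
which multiclass **ReliefF** (k = 10 nearest hits/misses, Manhattan
distance on range-normalised features) ranks; the top-42 subspace feeds
a quadratic discriminant, a degree-2 polynomial SVM ((x·y/d + 1)², C=1)
or bagged trees, evaluated by stratified 10-fold cross-validation with
per-class accuracy, precision, recall and F1. A per-feature
Kruskal–Wallis test screens the retained subspace for class differences.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices, and `docs/uci_runbook.md` for running against the public UCI
"sEMG for Basic Hand movements" recordings.

## Worked example

```python
import numpy as np
import semgrasp as sg

fs = 500.0
t = np.arange(2000) / fs
signal = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t)
ms = sg.vmd_decompose(signal, fs, sg.VmdConfig(K=2, alpha=2000))
print(ms.center_freqs.round(2))
```

prints `[ 49.99 150.  ]` — each tone captured by its own mode (mode-tone
correlations 0.998 and 0.999), with additive reconstruction error
2.2e-18. The full chain on synthetic data
(`examples/04_select_and_classify.py`):

```text
feature table: 60 windows x 88 features
top 5 features by ReliefF weight:
  ch1/VMF05/MNF
  ch1/VMF05/MDF
  ch1/VMF04/MNF
  ch2/VMF04/MDF
  ch1/VMF04/MDF
Kruskal-Wallis screen: 42/42 features differ across classes at p < 0.05
       Accuracy Precision   Recall    F1
Grasps
CY      100.00%   100.00%  100.00%  1.00
...
Mean accuracy over folds: 100.00%
```

ReliefF puts spectral features (MNF/MDF) of mid-band modes on top —
exactly the features that distinguish the generator's per-class
frequency bands — and the selected subspace separates the six classes
completely. Real sEMG is harder than this generator (see
`docs/methods.md`); the numbers demonstrate the machinery, not clinical
performance.

Each script in `examples/` is a short narrative of one capability:
simulation/segmentation, VMD, feature extraction, selection +
classification, and the three protocol sweeps. A thin CLI wraps the same
functions (`semgrasp simulate|decompose|features|select|evaluate|sweep`).

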