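"""The three evaluation protocols: mode-count sweep, dimension sweep, noise.

All protocols share one pipeline: segment each trial with a sliding
window, decompose every window channel with VMD, extract the four
features per component, optionally rank/select with ReliefF, and score a
classifier by stratified 10-fold cross-validation per subject.  Each
protocol varies exactly one axis:

* :func:`sweep_vmf_counts` — the number of decomposition modes K;
* :func:`sweep_dimensions` — the retained feature-space dimension d
  (one ReliefF ranking computed once and reused across d);
* :func:`noise_robustness` — additive Gaussian white noise whose std is
  a stated fraction of each channel's signal std.

Every run is fully determined by its configuration and seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import crossval_evaluate
from .features import DEFAULT_PEEN_DELAY, DEFAULT_PEEN_M, extract_features, feature_names
from .io import EmgRecording
from .relieff import ReliefFConfig, relieff_weights, select_top
from .segment import DEFAULT_WINDOW_SIZE, DEFAULT_WINDOW_STEP, Window, segment_all
from .vmd import VmdConfig, vmd_decompose_batch

__all__ = [
    "SweepResult",
    "compute_feature_table",
    "sweep_vmf_counts",
    "sweep_dimensions",
    "add_noise",
    "noise_robustness",
]

logger = logging.getLogger(__name__)

#: Windows decomposed per VMD batch call (keeps peak memory modest).
_VMD_CHUNK = 128


@dataclass
class SweepResult:
    """Per-subject mean accuracies over one swept parameter."""

    axis: str
    values: list
    accuracies: pd.DataFrame  # index = subjects, columns = values

    @property
    def best_setting(self) -> pd.Series:
        """The swept value attaining each subject's row maximum."""
        return self.accuracies.idxmax(axis=1)


def compute_feature_table(
    windows: list[Window],
    vmd_config: VmdConfig,
    *,
    peen_m: int = DEFAULT_PEEN_M,
    peen_delay: int = DEFAULT_PEEN_DELAY,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Decompose all windows and assemble the feature matrix.

    Returns ``(matrix, labels, names, groups)`` where ``groups`` carries
    each window's (subject, source-trial, label) identity for optional
    trial-grouped cross-validation.  Windows are decomposed channel-wise
    in batches; results are identical to one-at-a-time decomposition.
    """
    if not windows:
        raise ValueError("no windows to process")
    n_channels = windows[0].n_channels
    fs = windows[0].sample_rate_hz
    if any(w.n_channels != n_channels or w.sample_rate_hz != fs for w in windows):
        raise ValueError("windows must share channel count and sample rate")

    rows: list[np.ndarray] = []
    for start in range(0, len(windows), _VMD_CHUNK):
        chunk = windows[start : start + _VMD_CHUNK]
        # (n_windows * n_channels, L): channel-major per window.
        stack = np.concatenate([w.samples.T for w in chunk], axis=0)
        mode_sets = vmd_decompose_batch(stack, fs, vmd_config)
        for i, w in enumerate(chunk):
            per_channel = mode_sets[i * n_channels : (i + 1) * n_channels]
            fv = extract_features(
                per_channel,
                class_label=w.class_label,
                subject_id=w.subject_id,
                peen_m=peen_m,
                peen_delay=peen_delay,
            )
            rows.append(fv.values)
    matrix = np.vstack(rows)
    labels = np.asarray([w.class_label for w in windows], dtype=object)
    groups = np.asarray(
        [f"{w.subject_id}|{w.class_label}|{w.source_trial}" for w in windows],
        dtype=object,
    )
    return matrix, labels, feature_names(n_channels, vmd_config.K), groups


def _by_subject(recordings: list[EmgRecording]) -> dict[str, list[EmgRecording]]:
    out: dict[str, list[EmgRecording]] = {}
    for rec in recordings:
        out.setdefault(rec.subject_id, []).append(rec)
    return out


def sweep_vmf_counts(
    recordings: list[EmgRecording],
    counts: list[int],
    classifier_kinds: list[str],
    *,
    window_size: int = DEFAULT_WINDOW_SIZE,
    window_step: int = DEFAULT_WINDOW_STEP,
    vmd_config: VmdConfig = VmdConfig(),
    folds: int = 10,
    seed: int = 0,
) -> dict[str, SweepResult]:
    """Mean CV accuracy per subject for each mode count K (no selection).

    Each K gets a fresh decomposition of every window; the full
    ``channels x (K+1) x 4`` feature space is fed to each classifier.
    Returns one :class:`SweepResult` per classifier kind.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if sorted(counts) != list(counts):
        counts = sorted(counts)
    subjects = _by_subject(recordings)
    acc: dict[str, dict[str, dict[int, float]]] = {
        kind: {s: {} for s in subjects} for kind in classifier_kinds
    }
    for subject, recs in subjects.items():
        windows = segment_all(recs, window_size, window_step)
        for K in counts:
            cfg = VmdConfig(
                K=K, alpha=vmd_config.alpha, tau=vmd_config.tau, tol=vmd_config.tol,
                max_iter=vmd_config.max_iter, init_mode=vmd_config.init_mode,
                seed=vmd_config.seed,
            )
            X, y, _, _ = compute_feature_table(windows, cfg)
            for kind in classifier_kinds:
                report = crossval_evaluate(X, y, kind, folds=folds, seed=seed)
                acc[kind][subject][K] = report.mean_accuracy
    return {
        kind: SweepResult(
            axis="vmf_count",
            values=list(counts),
            accuracies=pd.DataFrame.from_dict(acc[kind], orient="index")[list(counts)],
        )
        for kind in classifier_kinds
    }


def sweep_dimensions(
    features: np.ndarray,
    labels: np.ndarray,
    dims: list[int],
    classifier_kind: str = "svm_poly2",
    *,
    relieff_config: ReliefFConfig = ReliefFConfig(),
    subject_id: str = "s1",
    folds: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Mean CV accuracy for each retained dimension of one fixed ranking.

    The ReliefF ranking is computed once on the full table and reused for
    every d, so d = n_features reproduces the no-selection evaluation
    exactly.  Dims are reported ascending.
    """
    if not dims:
        raise ValueError("dims must be non-empty")
    X = np.asarray(features, dtype=np.float64)
    dims = sorted(dims)
    if dims[-1] > X.shape[1]:
        raise ValueError(f"max dim {dims[-1]} exceeds feature count {X.shape[1]}")
    weights = relieff_weights(X, labels, relieff_config)
    row: dict[int, float] = {}
    for d in dims:
        sel = select_top(weights, d)
        report = crossval_evaluate(X[:, sel.selected_indices], labels,
                                   classifier_kind, folds=folds, seed=seed)
        row[d] = report.mean_accuracy
    return SweepResult(
        axis="dimension",
        values=dims,
        accuracies=pd.DataFrame({d: [row[d]] for d in dims}, index=[subject_id]),
    )


def add_noise(recording: EmgRecording, level: float, seed: int) -> EmgRecording:
    """Return a copy with additive zero-mean Gaussian white noise.

    ``level`` is the noise std as a fraction of each channel's own sample
    std (a noise level of 0.6 adds noise with 60% of the signal's std).
    The original recording is untouched; level 0 returns an identical
    copy.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    samples = recording.samples.copy()
    if level > 0:
        rng = np.random.default_rng(seed)
        sigma = samples.std(axis=0)
        samples = samples + rng.standard_normal(samples.shape) * (level * sigma)
    return EmgRecording(
        subject_id=recording.subject_id,
        class_label=recording.class_label,
        trial_index=recording.trial_index,
        sample_rate_hz=recording.sample_rate_hz,
        samples=samples,
    )


def noise_robustness(
    recordings: list[EmgRecording],
    levels: list[float],
    classifier_kinds: list[str],
    *,
    window_size: int = DEFAULT_WINDOW_SIZE,
    window_step: int = DEFAULT_WINDOW_STEP,
    vmd_config: VmdConfig = VmdConfig(),
    relieff_config: ReliefFConfig = ReliefFConfig(),
    dimension: int | None = None,
    folds: int = 10,
    seed: int = 0,
    mode: str = "perturb_all",
) -> pd.DataFrame:
    """Mean CV accuracy per (noise level, classifier kind).

    ``mode="perturb_all"`` (default) adds noise to every recording and
    runs the standard pipeline + CV on the perturbed data, i.e. the
    perturbed signals are what the recognition method receives.
    ``mode="train_clean"`` trains each fold on clean features and tests
    on the noisy features of the held-out windows.  If ``dimension`` is
    given, a ReliefF ranking from the clean data fixes the retained
    feature subset for every level.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if mode not in ("perturb_all", "train_clean"):
        raise ValueError(f"unknown mode {mode!r}")
    levels = list(levels)

    clean_windows = segment_all(recordings, window_size, window_step)
    X_clean, y, _, _ = compute_feature_table(clean_windows, vmd_config)
    keep = slice(None)
    if dimension is not None:
        weights = relieff_weights(X_clean, y, relieff_config)
        keep = select_top(weights, dimension).selected_indices

    results: dict[float, dict[str, float]] = {}
    for li, level in enumerate(levels):
        if level == 0:
            X_noisy = X_clean
        else:
            noisy = [
                add_noise(rec, level, seed=seed + 1_000_003 * (li + 1) + ri)
                for ri, rec in enumerate(recordings)
            ]
            noisy_windows = segment_all(noisy, window_size, window_step)
            X_noisy, _, _, _ = compute_feature_table(noisy_windows, vmd_config)
        results[level] = {}
        for kind in classifier_kinds:
            if mode == "perturb_all":
                report = crossval_evaluate(X_noisy[:, keep], y, kind,
                                           folds=folds, seed=seed)
                results[level][kind] = report.mean_accuracy
            else:
                results[level][kind] = _train_clean_test_noisy(
                    X_clean[:, keep], X_noisy[:, keep], y, kind, folds, seed
                )
    return pd.DataFrame.from_dict(results, orient="index")[list(classifier_kinds)]


def _train_clean_test_noisy(X_clean, X_noisy, y, kind, folds, seed) -> float:
    from sklearn.model_selection import StratifiedKFold

    from .classify import train_classifier

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in splitter.split(X_clean, y):
        model = train_classifier(X_clean[train], y[train], kind, seed=seed)
        accs.append(float(np.mean(model.predict(X_noisy[test]) == y[test])))
    return float(np.mean(accs))
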