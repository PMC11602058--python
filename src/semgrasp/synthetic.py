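"""Synthetic labelled 2-channel sEMG datasets for end-to-end testing.

Each grasp class is emulated as band-limited Gaussian noise (a
class-specific pass band inside the 15-245 Hz range that survives the
acquisition chain's filtering) shaped by a class-specific amplitude
envelope (contraction bursts), mixed onto the two channels with
class-specific gains, plus a white noise floor.  This captures what the
feature pipeline actually measures — spectral location (MDF/MNF),
amplitude (MAV) and irregularity (PeEn) — while deliberately remaining
much easier to separate than real sEMG: there are no motor-unit action
potentials, no electrode drift, no inter-trial electrode shift and no
muscle fatigue.  Results on this generator exercise the machinery, not
the physiology.

Defaults mirror the target acquisition: 6 grasp classes, 30 trials per
class per subject, 6 s per trial at 500 Hz, 2 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import bandpass
from .io import GRASP_LABELS, DatasetManifest, EmgRecording, ManifestEntry

__all__ = ["SynthConfig", "generate_dataset"]

#: Default per-class pass bands (Hz): disjoint, inside the 15-245 Hz range.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (30.0, 50.0),
    (60.0, 80.0),
    (90.0, 110.0),
    (120.0, 140.0),
    (150.0, 170.0),
    (180.0, 200.0),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; every default matches the emulated acquisition."""

    n_subjects: int = 1
    n_classes: int = 6
    trials_per_class: int = 30
    duration_s: float = 6.0
    sample_rate_hz: float = 500.0
    n_channels: int = 2
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    #: Depth of the contraction-burst amplitude modulation in [0, 1).
    envelope_depth: float = 0.5
    #: White-noise floor std relative to the band-limited signal's std.
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.n_classes > len(GRASP_LABELS):
            raise ValueError(f"n_classes must be in [2, {len(GRASP_LABELS)}]")
        if len(self.bands) < self.n_classes:
            raise ValueError("need one pass band per class")
        nyq = self.sample_rate_hz / 2.0
        for lo, hi in self.bands[: self.n_classes]:
            if not 15.0 < lo < hi < min(245.0, nyq):
                raise ValueError(
                    f"band ({lo}, {hi}) must lie strictly inside (15, {min(245.0, nyq)}) Hz"
                )
        if not 0 <= self.envelope_depth < 1:
            raise ValueError("envelope_depth must be in [0, 1)")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")


def _envelope(n: int, class_idx: int, depth: float) -> np.ndarray:
    """Class-specific contraction profile: ``1 + depth sin`` bursts.

    Class ``c`` gets ``c + 1`` smooth bursts across the trial, so the
    amplitude trajectory (hence windowed MAV) differs by class.
    """
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    bursts = class_idx + 1
    return 1.0 + depth * np.sin(np.pi * bursts * t) ** 2


def generate_dataset(config: SynthConfig = SynthConfig()) -> tuple[
        list[EmgRecording], DatasetManifest]:
    """Generate recordings plus a manifest; bit-identical under a fixed seed."""
    n = int(round(config.duration_s * config.sample_rate_hz))
    labels = list(GRASP_LABELS[: config.n_classes])
    subjects = [f"s{i + 1}" for i in range(config.n_subjects)]
    root = np.random.default_rng(config.seed)
    recordings: list[EmgRecording] = []
    entries: list[ManifestEntry] = []
    for si, subject in enumerate(subjects):
        # Per-subject channel gains: both channels active for every class,
        # with a class-dependent balance (electrode placement surrogate).
        for ci, label in enumerate(labels):
            lo, hi = config.bands[ci]
            gains = np.array([1.0, 0.5 + 0.08 * ci])
            for trial in range(config.trials_per_class):
                rng = np.random.default_rng(
                    root.integers(0, 2**31 - 1)
                )
                base = bandpass(
                    rng.standard_normal(n), lo, hi, config.sample_rate_hz
                )
                base /= base.std()
                env = _envelope(n, ci, config.envelope_depth)
                sig = np.outer(base * env, gains)
                sig += config.noise_floor * rng.standard_normal(sig.shape)
                recordings.append(
                    EmgRecording(
                        subject_id=subject,
                        class_label=label,
                        trial_index=trial,
                        sample_rate_hz=config.sample_rate_hz,
                        samples=sig,
                    )
                )
                entries.append(
                    ManifestEntry(
                        subject_id=subject,
                        class_label=label,
                        trial_index=trial,
                        path=f"{subject}_{label}_{trial:03d}.csv",
                    )
                )
    manifest = DatasetManifest(
        subjects=subjects,
        labels=labels,
        sample_rate_hz=config.sample_rate_hz,
        n_channels=config.n_channels,
        trials=entries,
    )
    return recordings, manifest
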