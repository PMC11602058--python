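"""Reading and writing recordings, manifests and feature tables.

The native on-disk layout is deliberately plain: one delimited text file
per trial (one row per time sample, one column per channel, no header)
plus a YAML manifest carrying all metadata (subjects, label set, sampling
rate, and one entry per trial file).  A reader for the UCI "sEMG for
Basic Hand movements" MATLAB-container layout is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import loadmat

__all__ = [
    "GRASP_LABELS",
    "EmgRecording",
    "ManifestEntry",
    "DatasetManifest",
    "DataFormatError",
    "ChannelMismatchError",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "load_dataset",
    "save_dataset",
    "read_uci_mat",
    "write_feature_table",
    "read_feature_table",
]

logger = logging.getLogger(__name__)

#: The six grasp classes: cylindrical, tip, hook, palmar, spherical, lateral.
GRASP_LABELS: tuple[str, ...] = ("CY", "TI", "HO", "PA", "SP", "LA")

#: Variable-name stems used by the UCI MATLAB containers, mapped to labels.
_UCI_STEMS: dict[str, str] = {
    "cyl": "CY",
    "tip": "TI",
    "hook": "HO",
    "palm": "PA",
    "spher": "SP",
    "lat": "LA",
}


class DataFormatError(ValueError):
    """A trial file or container holds something other than finite numbers."""


class ChannelMismatchError(ValueError):
    """Channel count (or per-channel trial count) disagrees with the manifest."""


@dataclass
class EmgRecording:
    """One labelled multi-channel sEMG trial.

    ``samples`` has shape ``(n_samples, n_channels)``; amplitudes are in
    whatever units the acquisition produced (typically mV) — no feature
    downstream depends on absolute calibration.
    """

    subject_id: str
    class_label: str
    trial_index: int
    sample_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a non-empty (n_samples, n_channels) matrix")
        if not np.all(np.isfinite(self.samples)):
            raise DataFormatError("recording contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class ManifestEntry:
    subject_id: str
    class_label: str
    trial_index: int
    path: str


@dataclass
class DatasetManifest:
    """Index of a dataset directory: label set, subjects, one entry per trial."""

    subjects: list[str]
    labels: list[str]
    sample_rate_hz: float
    n_channels: int
    trials: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("manifest label set must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("manifest labels must be unique")


def read_recording(path: str | Path, entry: ManifestEntry, *, sample_rate_hz: float,
                   n_channels: int) -> EmgRecording:
    """Parse one delimited trial file against its manifest entry.

    Raises ``FileNotFoundError`` for a missing file, ``DataFormatError``
    for non-numeric or non-finite cells and ``ChannelMismatchError`` when
    the column count differs from the manifest's channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial file not found: {path}")
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise DataFormatError(f"non-finite value in {path}")
    if values.shape[1] != n_channels:
        raise ChannelMismatchError(
            f"{path}: file has {values.shape[1]} channels, manifest declares {n_channels}"
        )
    return EmgRecording(
        subject_id=entry.subject_id,
        class_label=entry.class_label,
        trial_index=entry.trial_index,
        sample_rate_hz=sample_rate_hz,
        samples=values,
    )


def write_recording(recording: EmgRecording, path: str | Path) -> None:
    """Write one trial as comma-delimited text, one row per time sample."""
    np.savetxt(path, recording.samples, delimiter=",", fmt="%.10g")


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    doc = {
        "subjects": list(manifest.subjects),
        "labels": list(manifest.labels),
        "sample_rate_hz": float(manifest.sample_rate_hz),
        "n_channels": int(manifest.n_channels),
        "trials": [
            {
                "subject_id": e.subject_id,
                "class_label": e.class_label,
                "trial_index": int(e.trial_index),
                "path": e.path,
            }
            for e in manifest.trials
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | Path) -> DatasetManifest:
    doc = yaml.safe_load(Path(path).read_text())
    return DatasetManifest(
        subjects=list(doc["subjects"]),
        labels=list(doc["labels"]),
        sample_rate_hz=float(doc["sample_rate_hz"]),
        n_channels=int(doc["n_channels"]),
        trials=[ManifestEntry(**e) for e in doc["trials"]],
    )


def save_dataset(recordings: list[EmgRecording], manifest: DatasetManifest,
                 directory: str | Path) -> Path:
    """Write trial files plus ``manifest.yaml`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(recordings) != len(manifest.trials):
        raise ValueError("recording count and manifest trial count differ")
    for rec, entry in zip(recordings, manifest.trials):
        write_recording(rec, directory / entry.path)
    manifest_path = directory / "manifest.yaml"
    write_manifest(manifest, manifest_path)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> tuple[list[EmgRecording], DatasetManifest]:
    """Read every trial referenced by a manifest file."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    recordings = [
        read_recording(
            base / e.path, e,
            sample_rate_hz=manifest.sample_rate_hz,
            n_channels=manifest.n_channels,
        )
        for e in manifest.trials
    ]
    for rec in recordings:
        if rec.class_label not in manifest.labels:
            raise ValueError(f"label {rec.class_label!r} not in manifest label set")
    return recordings, manifest


def read_uci_mat(path: str | Path, *, sample_rate_hz: float = 500.0,
                 subject_id: str = "s1") -> list[EmgRecording]:
    """Read one subject's MATLAB container in the UCI basic-hand-movements layout.

    The container holds one matrix per grasp per channel named
    ``<stem>_ch1`` / ``<stem>_ch2`` (stems ``cyl, tip, hook, palm, spher,
    lat``), rows = trials and columns = samples.  Channels are paired by
    row (trial) index, which is how the acquisition interleaves them.
    Returns one two-channel :class:`EmgRecording` per trial per grasp.
    """
    raw = loadmat(str(path))
    data = {k: v for k, v in raw.items() if not k.startswith("__")}
    if not data:
        logger.warning("UCI container %s holds no data variables", path)
        return []
    grasps: dict[str, dict[int, np.ndarray]] = {}
    for name, mat in data.items():
        stem, _, ch = name.rpartition("_")
        if stem not in _UCI_STEMS or not ch.startswith("ch"):
            raise DataFormatError(f"unrecognised variable {name!r} in {path}")
        grasps.setdefault(stem, {})[int(ch[2:])] = np.asarray(mat, dtype=np.float64)
    recordings: list[EmgRecording] = []
    for stem in sorted(grasps):
        chans = grasps[stem]
        mats = [chans[c] for c in sorted(chans)]
        n_trials = {m.shape[0] for m in mats}
        if len(chans) < 2 or len(n_trials) != 1:
            raise ChannelMismatchError(
                f"{path}: grasp {stem!r} has inconsistent channels/trial counts"
            )
        label = _UCI_STEMS[stem]
        for t in range(mats[0].shape[0]):
            samples = np.column_stack([m[t] for m in mats])
            recordings.append(
                EmgRecording(
                    subject_id=subject_id,
                    class_label=label,
                    trial_index=t,
                    sample_rate_hz=sample_rate_hz,
                    samples=samples,
                )
            )
    return recordings


def write_feature_table(matrix: np.ndarray, labels: list[str] | np.ndarray,
                        names: list[str], path: str | Path) -> None:
    """Write a feature matrix as CSV: named feature columns + final ``label``.

    Values are serialised at full double precision so a round trip is
    bit-exact.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if matrix.size == 0:
        matrix = matrix.reshape(0, len(names))
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    if matrix.shape[0] != len(labels):
        raise ValueError(
            f"row count {matrix.shape[0]} does not match label count {len(labels)}"
        )
    if matrix.shape[1] != len(names):
        raise ValueError("column count does not match feature-name count")
    df = pd.DataFrame(matrix, columns=names)
    df["label"] = list(labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a feature-table CSV; returns ``(matrix, labels, names)``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise DataFormatError(f"{path}: feature table lacks a 'label' column")
    labels = df.pop("label").to_numpy(dtype=object)
    return df.to_numpy(dtype=np.float64), labels, list(df.columns)
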