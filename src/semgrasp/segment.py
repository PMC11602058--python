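"""Sliding-window segmentation of recordings into fixed-length labelled windows."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EmgRecording

__all__ = ["Window", "RecordingTooShortError", "segment", "segment_all"]

#: Window length in samples used throughout (4 s at 500 Hz).
DEFAULT_WINDOW_SIZE = 2000
#: Hop between consecutive window starts, in samples.
DEFAULT_WINDOW_STEP = 80


class RecordingTooShortError(ValueError):
    """The recording holds fewer samples than one window."""


@dataclass
class Window:
    """A fixed-length segment ``[start_index, start_index + size)`` of a trial.

    Inherits its source recording's class label and subject; indexing is
    0-based and half-open.
    """

    samples: np.ndarray  # (L, n_channels)
    class_label: str
    subject_id: str
    source_trial: int
    start_index: int
    sample_rate_hz: float

    @property
    def size(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def segment(recording: EmgRecording, size: int = DEFAULT_WINDOW_SIZE,
            step: int = DEFAULT_WINDOW_STEP) -> list[Window]:
    """Cut a recording into overlapping windows of ``size`` samples every ``step``.

    Windows start at ``0, step, 2 step, ...``; the count is
    ``floor((n_samples - size) / step) + 1``.  Trailing samples that do
    not fill a final window are dropped.  A recording shorter than one
    window raises :class:`RecordingTooShortError` rather than silently
    yielding nothing.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    n = recording.n_samples
    if size > n:
        raise RecordingTooShortError(
            f"recording has {n} samples, shorter than one window of {size}"
        )
    starts = range(0, n - size + 1, step)
    return [
        Window(
            samples=recording.samples[s : s + size],
            class_label=recording.class_label,
            subject_id=recording.subject_id,
            source_trial=recording.trial_index,
            start_index=s,
            sample_rate_hz=recording.sample_rate_hz,
        )
        for s in starts
    ]


def segment_all(recordings: list[EmgRecording], size: int = DEFAULT_WINDOW_SIZE,
                step: int = DEFAULT_WINDOW_STEP) -> list[Window]:
    """Segment each recording independently (never across trial boundaries)."""
    windows: list[Window] = []
    for rec in recordings:
        windows.extend(segment(rec, size, step))
    return windows
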