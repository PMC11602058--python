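"""Small filtering utilities (Butterworth band-pass, mains notch).

The target dataset arrives already band-passed (15-500 Hz) and notch
filtered at 50 Hz, so these helpers exist for synthesis and for users
with raw recordings; re-filtering pre-filtered data is not part of the
validated pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, iirnotch, sosfiltfilt, tf2sos


def bandpass(signal: np.ndarray, low_hz: float, high_hz: float, sample_rate: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = sample_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq} Hz)")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=np.float64), axis=-1)


def notch(signal: np.ndarray, freq_hz: float, sample_rate: float,
          quality: float = 30.0) -> np.ndarray:
    """Zero-phase notch (band-stop) filter, e.g. for 50 Hz mains interference."""
    b, a = iirnotch(freq_hz, quality, fs=sample_rate)
    sos = tf2sos(b, a)
    return sosfiltfilt(sos, np.asarray(signal, dtype=np.float64), axis=-1)
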