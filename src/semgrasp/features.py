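"""Per-component features: MAV, MDF, MNF and permutation entropy.

Four features are computed from every decomposed component (each VMF and
the residual) of every channel of a window:

* **MAV** — mean absolute value, ``(1/N) sum |x_i|``: a time-domain
  amplitude feature, homogeneous of degree 1 under amplitude scaling.
* **MDF** — median frequency: the frequency splitting the power spectrum
  into halves of equal power.
* **MNF** — mean frequency: the power-weighted average frequency
  ``sum f_j P_j / sum P_j``.
* **PeEn** — permutation entropy: the Shannon entropy (in nats) of the
  relative frequencies of ordinal (rank-order) patterns of the embedded
  series; bounded by ``ln(m!)`` and invariant under any strictly
  monotone amplitude transformation.

The spectrum behind MDF/MNF is a one-sided boxcar periodogram; Parseval
ties its total power to the signal's mean square.  The assembled feature
vector is ordered channel-major, component-second, feature-last, with
modes in ascending centre frequency and the residual as the final
component of each channel — for 2 channels, 10 modes + residual and 4
features this gives the 88-dimensional space the pipeline ranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .vmd import ModeSet

__all__ = [
    "SpectrumEstimate",
    "FeatureVector",
    "FEATURE_KINDS",
    "mav",
    "estimate_spectrum",
    "mdf",
    "mnf",
    "ordinal_pattern_probabilities",
    "peen",
    "extract_features",
    "feature_names",
]

logger = logging.getLogger(__name__)

FEATURE_KINDS: tuple[str, ...] = ("MAV", "MDF", "MNF", "PeEn")

#: Default permutation-entropy embedding dimension and delay.
DEFAULT_PEEN_M = 3
DEFAULT_PEEN_DELAY = 1


@dataclass
class SpectrumEstimate:
    """One-sided power spectrum: ``freqs`` ascending (Hz), ``powers >= 0``."""

    freqs: np.ndarray
    powers: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.powers = np.asarray(self.powers, dtype=np.float64)
        if self.freqs.size < 1 or self.freqs.shape != self.powers.shape:
            raise ValueError("freqs and powers must be equal-length, non-empty")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.powers < 0):
            raise ValueError("powers must be nonnegative")

    @property
    def total_power(self) -> float:
        return float(self.powers.sum())


@dataclass
class FeatureVector:
    """Ordered feature values with aligned names for one window."""

    values: np.ndarray
    names: list[str]
    class_label: str
    subject_id: str


def mav(signal: np.ndarray) -> float:
    """Mean absolute value ``(1/N) sum_i |x_i|``."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("MAV of an empty signal is undefined")
    return float(np.mean(np.abs(signal)))


def estimate_spectrum(signal: np.ndarray, sample_rate: float) -> SpectrumEstimate:
    """One-sided boxcar periodogram scaled to power (not density).

    With ``scaling="spectrum"`` the bin powers sum to the signal's mean
    square, so MDF/MNF see the raw spectral mass of Parseval's identity.
    No taper and no detrending: the decomposed components are already
    narrowband and near zero-mean.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2:
        raise ValueError("spectrum estimation needs at least 2 samples")
    freqs, powers = periodogram(
        signal, fs=sample_rate, window="boxcar", detrend=False, scaling="spectrum"
    )
    return SpectrumEstimate(freqs=freqs, powers=powers)


def mdf(spectrum: SpectrumEstimate) -> float:
    """Median frequency: the bin where cumulative power first reaches half.

    Discrete bins rarely split the power exactly in half; the smallest
    ``j`` with ``sum_{i<=j} P_i >= (1/2) sum P`` is returned, which makes
    ties deterministic.  Raises on zero total power.
    """
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("MDF undefined for a spectrum with zero total power")
    cum = np.cumsum(spectrum.powers)
    j = int(np.searchsorted(cum, 0.5 * total))
    return float(spectrum.freqs[j])


def mnf(spectrum: SpectrumEstimate) -> float:
    """Mean (power-weighted average) frequency ``sum f_j P_j / sum P_j``."""
    total = spectrum.total_power
    if total <= 0:
        raise ValueError("MNF undefined for a spectrum with zero total power")
    return float(np.dot(spectrum.freqs, spectrum.powers) / total)


def _ordinal_patterns(signal: np.ndarray, m: int, delay: int) -> np.ndarray:
    """Map each embedding vector to an integer encoding its ordinal pattern.

    Ranks are assigned by a stable ascending sort, so ties are broken by
    order of occurrence within the embedding vector.
    """
    n = signal.size - (m - 1) * delay
    # (n, m) embedding matrix of lagged samples
    idx = np.arange(n)[:, None] + delay * np.arange(m)[None, :]
    emb = signal[idx]
    ranks = np.argsort(np.argsort(emb, axis=1, kind="stable"), axis=1, kind="stable")
    # Encode the rank tuple in factorial-free base-m positional code.
    return (ranks * (m ** np.arange(m))[None, :]).sum(axis=1)


def ordinal_pattern_probabilities(signal: np.ndarray, m: int = DEFAULT_PEEN_M,
                                  delay: int = DEFAULT_PEEN_DELAY) -> np.ndarray:
    """Observed ordinal-pattern probabilities of the ``(m, delay)`` embedding.

    Returns the relative frequencies of the patterns that occur (at most
    ``m!`` values, each in ``(0, 1]``, summing to 1); the permutation
    entropy is the Shannon entropy of this distribution.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if m < 2:
        raise ValueError("embedding dimension m must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    n_vectors = signal.size - (m - 1) * delay
    if n_vectors < 1:
        raise ValueError(
            f"series of length {signal.size} too short for m={m}, delay={delay}"
        )
    codes = _ordinal_patterns(signal, m, delay)
    _, counts = np.unique(codes, return_counts=True)
    return counts / n_vectors


def peen(signal: np.ndarray, m: int = DEFAULT_PEEN_M,
         delay: int = DEFAULT_PEEN_DELAY) -> float:
    """Permutation entropy ``H_p(m) = -sum_j P_j ln P_j`` in nats.

    ``P_j`` are the relative frequencies of the ordinal patterns of the
    ``N - (m-1) delay`` embedding vectors; the result lies in
    ``[0, ln(m!)]``.
    """
    p = ordinal_pattern_probabilities(signal, m, delay)
    return float(-(p * np.log(p)).sum())


def feature_names(n_channels: int, K: int) -> list[str]:
    """Names like ``ch1/VMF03/MDF`` … ``ch2/RES/PeEn``, channel-major order."""
    components = [f"VMF{k + 1:02d}" for k in range(K)] + ["RES"]
    return [
        f"ch{c + 1}/{comp}/{feat}"
        for c in range(n_channels)
        for comp in components
        for feat in FEATURE_KINDS
    ]


def extract_features(mode_sets: list[ModeSet], *, class_label: str = "",
                     subject_id: str = "", peen_m: int = DEFAULT_PEEN_M,
                     peen_delay: int = DEFAULT_PEEN_DELAY) -> FeatureVector:
    """Assemble a window's feature vector from its per-channel mode sets.

    Each channel contributes ``(K + 1) * 4`` features: MAV, MDF, MNF and
    PeEn for every mode (ascending centre frequency) and for the
    residual.  A component with zero spectral power (e.g. an exactly-zero
    residual) gets MDF = MNF = 0 with a logged warning instead of
    aborting the batch.
    """
    if not mode_sets:
        raise ValueError("extract_features needs at least one ModeSet")
    K = mode_sets[0].K
    if any(ms.K != K for ms in mode_sets):
        raise ValueError("all channels must be decomposed with the same K")
    values: list[float] = []
    for ch, ms in enumerate(mode_sets):
        components = list(ms.modes) + [ms.residual]
        for ci, comp in enumerate(components):
            values.append(mav(comp))
            spec = estimate_spectrum(comp, ms.sample_rate_hz)
            if spec.total_power > 0:
                values.append(mdf(spec))
                values.append(mnf(spec))
            else:
                logger.warning(
                    "zero-power component (channel %d, component %d): MDF/MNF set to 0",
                    ch + 1, ci + 1,
                )
                values.extend([0.0, 0.0])
            values.append(peen(comp, peen_m, peen_delay))
    return FeatureVector(
        values=np.asarray(values, dtype=np.float64),
        names=feature_names(len(mode_sets), K),
        class_label=class_label,
        subject_id=subject_id,
    )


def max_peen(m: int) -> float:
    """Upper bound ``ln(m!)`` of the permutation entropy."""
    return math.log(math.factorial(m))
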