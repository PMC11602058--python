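"""Variational mode decomposition (VMD).

Decomposes a real 1-D signal into ``K`` narrowband modes ("variational mode
functions", VMFs) plus a residual by alternating spectral updates (ADMM):
each mode is refined with a Wiener-like filter centred on its current centre
frequency, the centre frequency is moved to the mode's spectral centre of
gravity, and an optional dual variable enforces exact reconstruction.

The mode update in the (one-sided) frequency domain is

    u_k <- (f - sum_{i != k} u_i + lambda/2) / (1 + 2 alpha (w - w_k)^2)

the centre-frequency update is

    w_k <- int w |u_k(w)|^2 dw / int |u_k(w)|^2 dw      (w >= 0)

and the dual ascent step is ``lambda <- lambda + tau (f - sum u_k)``.
Iteration stops when the summed relative change of all modes drops below
``tol`` or after ``max_iter`` sweeps.

Boundary effects are reduced by mirror-extending the signal by half its
length on each side before the spectral iteration and cropping afterwards.
The residual is defined as ``signal - sum(modes)``, so the additive
reconstruction ``sum(modes) + residual == signal`` holds to machine
precision by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numba
import numpy as np

__all__ = ["VmdConfig", "ModeSet", "vmd_decompose", "vmd_decompose_batch", "decompose_window"]

logger = logging.getLogger(__name__)

InitMode = Literal["zero", "uniform", "random"]


@dataclass(frozen=True)
class VmdConfig:
    """Hyperparameters of the variational mode decomposition.

    Parameters
    ----------
    K:
        Number of modes (VMFs) to extract.
    alpha:
        Bandwidth penalty; larger values force narrower modes.
    tau:
        Dual-ascent step. ``0`` disables the exact-reconstruction
        constraint (robust in the presence of broadband noise).
    tol:
        Convergence threshold on the summed relative squared change of
        the modes between sweeps.
    max_iter:
        Hard cap on the number of ADMM sweeps.
    init_mode:
        Centre-frequency initialisation: ``"zero"`` (all at 0),
        ``"uniform"`` (band midpoints ``(k + 1/2)/K`` of the Nyquist range)
        or ``"random"`` (sorted uniform draws; requires ``seed``).
    seed:
        Seed for ``init_mode="random"``.
    """

    K: int = 10
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init_mode: InitMode = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init_mode not in ("zero", "uniform", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "random" and self.seed is None:
            raise ValueError("init_mode='random' requires a seed")


@dataclass
class ModeSet:
    """Result of decomposing one single-channel signal.

    ``modes`` has shape ``(K, L)`` with rows ordered by ascending centre
    frequency; ``center_freqs`` are in Hz within ``[0, sample_rate / 2]``;
    ``residual`` is the input minus the mode sum, so the additive
    reconstruction is exact by construction.
    """

    modes: np.ndarray
    center_freqs: np.ndarray
    residual: np.ndarray
    n_iter: int
    converged: bool
    sample_rate_hz: float = field(default=0.0)

    @property
    def K(self) -> int:
        return self.modes.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Return ``sum(modes) + residual`` (equals the input signal)."""
        return self.modes.sum(axis=0) + self.residual


def _init_omegas(config: VmdConfig, n_signals: int) -> np.ndarray:
    """Initial centre frequencies in cycles/sample, shape (n_signals, K)."""
    K = config.K
    if config.init_mode == "zero":
        om = np.zeros((n_signals, K))
    elif config.init_mode == "uniform":
        om = np.tile(0.5 * (np.arange(K) + 0.5) / K, (n_signals, 1))
    else:
        rng = np.random.default_rng(config.seed)
        om = np.sort(rng.uniform(0.0, 0.5, size=(n_signals, K)), axis=1)
    return om


@numba.njit(cache=True, fastmath=True)
def _admm_sweeps(f_hat, freqs, omega, alpha, tau, tol, max_iter):  # pragma: no cover
    """Per-signal ADMM iteration; returns (u_hat, n_iter, converged).

    Plain loops so numba can fuse them; each signal iterates until its own
    mode change drops below ``tol``, so batch results equal single-signal
    runs exactly.
    """
    B, F = f_hat.shape
    K = omega.shape[1]
    u = np.zeros((B, K, F), dtype=np.complex128)
    lam = np.zeros(F, dtype=np.complex128)
    n_iter = np.zeros(B, dtype=np.int64)
    conv = np.zeros(B, dtype=np.bool_)
    for b in range(B):
        sum_u = np.zeros(F, dtype=np.complex128)
        lam[:] = 0.0
        it = 0
        while it < max_iter:
            it += 1
            diff_acc = 0.0
            for k in range(K):
                om = omega[b, k]
                old_energy = 0.0
                change = 0.0
                pw_sum = 0.0
                pw_mom = 0.0
                for j in range(F):
                    others = sum_u[j] - u[b, k, j]
                    d = freqs[j] - om
                    denom = 1.0 + 2.0 * alpha * d * d
                    newv = (f_hat[b, j] - others + 0.5 * lam[j]) / denom
                    old = u[b, k, j]
                    old_energy += old.real * old.real + old.imag * old.imag
                    dv = newv - old
                    change += dv.real * dv.real + dv.imag * dv.imag
                    u[b, k, j] = newv
                    sum_u[j] = others + newv
                    p = newv.real * newv.real + newv.imag * newv.imag
                    pw_sum += p
                    pw_mom += p * freqs[j]
                if old_energy > 0.0:
                    diff_acc += change / old_energy
                if pw_sum > 0.0:
                    omega[b, k] = pw_mom / pw_sum
            if tau > 0.0:
                for j in range(F):
                    lam[j] += tau * (f_hat[b, j] - sum_u[j])
            # The first sweep only populates the modes from zero; a
            # convergence decision needs two comparable iterates.
            if it > 1 and diff_acc < tol:
                conv[b] = True
                break
        n_iter[b] = it
    return u, n_iter, conv


def vmd_decompose_batch(
    signals: np.ndarray, sample_rate: float, config: VmdConfig
) -> list[ModeSet]:
    """Decompose a batch of equal-length signals with shared hyperparameters.

    The ADMM updates for each signal are independent; batching only
    amortises array overhead.  Each signal keeps its own convergence
    state: once a signal's mode change drops below ``tol`` its iterate is
    frozen, so results are identical to decomposing it alone.

    Parameters
    ----------
    signals:
        Array of shape ``(B, L)`` with ``L >= 2 K``, all values finite.
    sample_rate:
        Sampling rate in Hz (sets the frequency scale of the output).
    config:
        VMD hyperparameters shared across the batch.

    Returns
    -------
    list of ModeSet, one per input row, modes sorted by centre frequency.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim == 1:
        signals = signals[None, :]
    B, L = signals.shape
    if not np.all(np.isfinite(signals)):
        raise ValueError("VMD input contains non-finite values")
    if L < 2 * config.K:
        raise ValueError(f"signal length {L} too short for K={config.K} (need >= 2K)")
    K = config.K

    # Mirror-extend by L/2 on each side: total length T = 2 * L.
    half = L // 2
    ext = np.concatenate(
        [signals[:, half - 1 :: -1], signals, signals[:, : L - half - 1 : -1]], axis=1
    )
    T = ext.shape[1]
    F = T // 2 + 1
    f_hat = np.fft.rfft(ext, axis=1)  # (B, F) one-sided spectrum
    freqs = np.arange(F) / T  # cycles/sample, 0 .. 0.5

    omega = _init_omegas(config, B)  # (B, K), cycles/sample
    u_hat, n_iter, converged = _admm_sweeps(
        f_hat, freqs, omega, config.alpha, config.tau, config.tol, config.max_iter
    )
    n_unconverged = int(B - converged.sum())
    if n_unconverged:
        logger.warning(
            "VMD did not converge within %d iterations for %d of %d signals",
            config.max_iter,
            n_unconverged,
            B,
        )

    # Back to the time domain; crop the mirror extension.
    modes_ext = np.fft.irfft(u_hat, n=T, axis=2)
    modes = modes_ext[:, :, half : half + L]

    results: list[ModeSet] = []
    nyquist = sample_rate / 2.0
    for b in range(B):
        order = np.argsort(omega[b], kind="stable")
        m = np.ascontiguousarray(modes[b, order])
        cf = omega[b, order] * sample_rate
        cf = np.clip(cf, 0.0, nyquist)
        residual = signals[b] - m.sum(axis=0)
        results.append(
            ModeSet(
                modes=m,
                center_freqs=cf,
                residual=residual,
                n_iter=int(n_iter[b]),
                converged=bool(converged[b]),
                sample_rate_hz=float(sample_rate),
            )
        )
    return results


def vmd_decompose(signal: np.ndarray, sample_rate: float, config: VmdConfig) -> ModeSet:
    """Decompose one single-channel signal into ``config.K`` modes + residual.

    See :func:`vmd_decompose_batch` for the algorithm; this is the
    single-signal entry point.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("vmd_decompose expects a 1-D signal")
    return vmd_decompose_batch(signal[None, :], sample_rate, config)[0]


def decompose_window(window, config: VmdConfig) -> list[ModeSet]:
    """Decompose every channel of a window; returns one ModeSet per channel.

    ``window`` is any object with ``samples`` of shape ``(L, n_channels)``
    and ``sample_rate_hz`` (a :class:`~semgrasp.segment.Window` or an
    :class:`~semgrasp.io.EmgRecording`).
    """
    samples = np.asarray(window.samples, dtype=np.float64)
    if samples.ndim == 1:
        samples = samples[:, None]
    return vmd_decompose_batch(samples.T, window.sample_rate_hz, config)
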