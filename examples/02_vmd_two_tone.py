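"""Decompose a two-tone signal with VMD and inspect the recovered modes.

A 50 Hz + 150 Hz mixture decomposed with K=2 should yield one narrowband
mode per tone, centre frequencies on the tones, and an exact additive
reconstruction (modes + residual = input).
"""

import numpy as np

import semgrasp as sg

fs = 500.0
t = np.arange(2000) / fs
signal = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t)

ms = sg.vmd_decompose(signal, fs, sg.VmdConfig(K=2, alpha=2000))
print(f"centre frequencies: {ms.center_freqs.round(2)} Hz "
      f"(true tones at 50 and 150 Hz)")
print(f"converged: {ms.converged} after {ms.n_iter} iterations")

err = np.linalg.norm(ms.reconstruct() - signal) / np.linalg.norm(signal)
print(f"reconstruction relative error: {err:.2e}  (residual is input - sum of modes)")
for k in (0, 1):
    corr = np.corrcoef(ms.modes[k], np.sin(2 * np.pi * (50, 150)[k] * t))[0, 1]
    print(f"mode {k + 1} correlation with its source tone: {corr:.4f}")
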