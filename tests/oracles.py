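"""Independent brute-force oracles used to pin down the fast implementations.

Everything here is written as plain loops / direct library calls so it
shares no code path with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
import scipy.signal


def brute_wvd(z: np.ndarray, rate: float, lag_window_len: int) -> np.ndarray:
    """O(N² · Nτ) discrete pseudo-WVD: explicit instantaneous
    autocorrelation and an explicit DFT sum over half-lags."""
    z = np.asarray(z, dtype=complex)
    n = z.size
    h = min(lag_window_len // 2, (n - 1) // 2)
    out = np.zeros((n, n))
    for t in range(n):
        for k in range(n):
            acc = 0.0 + 0.0j
            for m in range(-h, h + 1):
                if 0 <= t + m < n and 0 <= t - m < n:
                    acc += (
                        z[t + m]
                        * np.conj(z[t - m])
                        * np.exp(-2j * np.pi * m * k / n)
                    )
            out[t, k] = acc.real * 2.0 / rate
    return out


def brute_direction_map(
    values: np.ndarray, kernels: dict[float, np.ndarray]
) -> np.ndarray:
    """Argmax-over-angles via scipy.signal.convolve2d, smallest angle wins."""
    src = np.abs(values)
    angles = sorted(kernels)
    resp = np.stack(
        [
            np.abs(scipy.signal.convolve2d(src, kernels[a], mode="same"))
            for a in angles
        ]
    )
    best = resp.max(axis=0)
    out = np.empty_like(src)
    for i in range(src.shape[0]):
        for j in range(src.shape[1]):
            for ai, a in enumerate(angles):
                if resp[ai, i, j] >= best[i, j] * (1 - 1e-9):
                    out[i, j] = a
                    break
    return out


def stft_peak_if(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous-frequency estimate from short-time spectral peaks."""
    f, t, s = scipy.signal.stft(
        x, fs=rate, nperseg=64, noverlap=56, nfft=1024, padded=False, boundary=None
    )
    peak = f[np.argmax(np.abs(s), axis=0)]
    return t, peak
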