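"""Quadratic time-frequency analysis: Wigner-Ville distribution and its
adaptive directional smoothing.

The Wigner-Ville distribution (WVD) of the analytic associate ``z(t)`` of a
real signal,

    W(t, f) = ∫ z(t + τ/2) z*(t - τ/2) e^{-j2πfτ} dτ,

localises tones and impulses perfectly but produces oscillatory cross-terms
for multicomponent signals.  The adaptive directional TFD (ADTFD) suppresses
them by convolving the WVD at every time-frequency point with an anisotropic
kernel whose major axis follows the local ridge orientation:

    ρ(t, f) = W(t, f) **_{t,f} γ_{θ(t,f)}(t, f),

where the orientation map θ(t, f) is the angle (on a quantised grid over
[0°, 180°)) that maximises the magnitude of the directional-filter response.
Ridges parallel to the time axis (tones, slow chirps) come out near 0°;
ridges parallel to the frequency axis (spikes) near 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.fft
import scipy.signal

__all__ = [
    "SampledSignal",
    "TimeFrequencyDistribution",
    "KernelParams",
    "DirectionMap",
    "analytic_signal",
    "wvd",
    "directional_kernel",
    "direction_map",
    "adtfd",
    "compute_adtfd",
    "top_energy_mask",
]

# relative tolerance for declaring directional responses tied (smallest
# angle wins among ties)
_TIE_RTOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when an input violates an operation's contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid range."""


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real signal (amplitudes in µV)."""

    samples: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ConfigError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidInputError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class TimeFrequencyDistribution:
    """Real-valued TF energy distribution on a rectangular grid.

    ``values`` has one row per time sample and one column per frequency bin;
    the frequency axis covers the analytic band [0, rate/2) with uniform bin
    width rate/(2 * nbins).
    """

    values: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    rate: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "time_axis", np.asarray(self.time_axis, dtype=float))
        object.__setattr__(self, "freq_axis", np.asarray(self.freq_axis, dtype=float))
        if v.shape != (self.time_axis.size, self.freq_axis.size):
            raise InvalidInputError("matrix shape does not match axis lengths")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise InvalidInputError("frequency axis must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("TFD values must be finite")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def df(self) -> float:
        return (self.rate / 2.0) / self.freq_axis.size


@dataclass(frozen=True)
class KernelParams:
    """Directional smoothing-kernel configuration.

    ``a`` and ``b`` are reciprocal length scales (grid units) along the
    kernel's major and minor axes: the Gaussian std along the major axis is
    1/(a*sqrt(2)) grid points.  Defaults give a major-axis std of 12 points
    and a minor-axis std of 2 points on a 256-point grid, with the support
    truncated at three major-axis stds.  ``lag_window_len`` is the odd
    pseudo-WVD lag-window length; None means the full (odd-truncated) signal
    length.
    """

    a: float = 1.0 / (12.0 * np.sqrt(2.0))
    b: float = 1.0 / (2.0 * np.sqrt(2.0))
    theta_step: float = 3.0
    support_halfwidth: int = 36
    lag_window_len: int | None = None
    second_derivative: bool = True  # (1 - a^2 t_theta^2) factor; False = pure Gaussian

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("kernel scales a, b must be positive")
        if not (0 < self.theta_step <= 180) or (180.0 % self.theta_step) != 0:
            raise ConfigError("theta_step must divide 180")
        if self.support_halfwidth < 1:
            raise ConfigError("support_halfwidth must be >= 1")
        if self.lag_window_len is not None and self.lag_window_len % 2 == 0:
            raise ConfigError("lag_window_len must be odd")

    @property
    def theta_grid(self) -> np.ndarray:
        return np.arange(0.0, 180.0, self.theta_step)


@dataclass(frozen=True)
class DirectionMap:
    """Per-TF-point ridge orientation in degrees, values on ``theta_grid``."""

    values: np.ndarray
    theta_grid: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "theta_grid", np.asarray(self.theta_grid, dtype=float))
        if not np.isin(np.unique(self.values), self.theta_grid).all():
            raise InvalidInputError("direction values must lie on the angle grid")


def top_energy_mask(values: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Boolean mask of the highest-|value| points carrying ``fraction`` of
    the total absolute energy — the ridge crest region of a TFD."""
    e = np.abs(np.asarray(values, dtype=float))
    flat = np.sort(e.ravel())[::-1]
    csum = np.cumsum(flat)
    if csum[-1] == 0:
        return np.zeros_like(e, dtype=bool)
    k = int(np.searchsorted(csum, fraction * csum[-1]))
    thresh = flat[min(k, flat.size - 1)]
    return e >= thresh


def analytic_signal(x: SampledSignal | np.ndarray) -> np.ndarray:
    """Analytic associate of a real signal (Hilbert transform).

    The returned complex sequence has the same length, its real part equals
    the input, and its spectrum vanishes on negative-frequency bins.
    """
    samples = x.samples if isinstance(x, SampledSignal) else np.asarray(x, dtype=float)
    if not np.all(np.isfinite(samples)):
        raise InvalidInputError("input must be finite")
    return scipy.signal.hilbert(samples)


def wvd(
    z: np.ndarray,
    rate: float,
    lag_window_len: int | None = None,
    nbins: int | None = None,
) -> TimeFrequencyDistribution:
    """Discrete (pseudo-)Wigner-Ville distribution of a complex signal.

    Computed from the instantaneous autocorrelation over half-lags
    ``K(n, m) = z[n+m] z*[n-m]`` (zero outside the record and outside the odd
    lag window), Fourier-transformed over m.  Frequency bin k maps to
    ``k * rate / (2 * nbins)`` Hz, so the axis spans the analytic band
    [0, rate/2).  Scaled by 2/rate so that the time marginal
    Σ_k W(n,k)·Δf equals |z(n)|² exactly.
    """
    z = np.asarray(z, dtype=complex)
    n_samp = z.size
    if lag_window_len is None:
        lag_window_len = n_samp if n_samp % 2 == 1 else n_samp - 1
    if lag_window_len % 2 == 0:
        raise ConfigError("lag_window_len must be odd")
    if lag_window_len > n_samp:
        raise ConfigError("lag_window_len cannot exceed the signal length")
    if nbins is None:
        nbins = n_samp
    half = lag_window_len // 2
    h = min(half, (nbins - 1) // 2)  # avoid ±m collision at the wrap bin

    # K[n, m mod nbins] = z[n+m] conj(z[n-m]); vectorized over time
    kern = np.zeros((n_samp, nbins), dtype=complex)
    n_idx = np.arange(n_samp)
    for m in range(-h, h + 1):
        lo = max(0, -m, m)
        hi = min(n_samp, n_samp - m, n_samp + m)
        if lo >= hi:
            continue
        rows = n_idx[lo:hi]
        kern[rows, m % nbins] = z[rows + m] * np.conj(z[rows - m])

    spec = scipy.fft.fft(kern, axis=1)
    resid = np.abs(spec.imag).sum()
    total = np.abs(spec).sum()
    values = spec.real * (2.0 / rate)
    time_axis = n_idx / rate
    freq_axis = np.arange(nbins) * rate / (2.0 * nbins)
    tfd = TimeFrequencyDistribution(values, time_axis, freq_axis, rate)
    if total > 0 and resid / total > 1e-8:
        # K(n,m) is Hermitian in m only for untruncated lags; warn-level check
        import warnings

        warnings.warn(
            f"WVD imaginary residue {resid / total:.2e} of total energy",
            RuntimeWarning,
            stacklevel=2,
        )
    return tfd


def directional_kernel(theta: float, params: KernelParams, kind: str = "smooth") -> np.ndarray:
    """Anisotropic directional filter oriented at ``theta`` degrees.

    Both kinds evaluate ab/(2π) · exp(-a²tθ² - b²fθ²) times a quadratic
    factor on the integer grid, with rotated coordinates
    tθ = t·cosθ + f·sinθ and fθ = f·cosθ - t·sinθ:

    * ``kind="smooth"`` — the adaptive-smoothing kernel, factor
      (1 - a²tθ²) along the major axis (pure Gaussian when
      ``second_derivative`` is off), normalised to unit signed sum so the
      filter has unit DC gain and smoothing preserves energy.
    * ``kind="ridge"`` — the orientation-estimation filter, factor
      (1 - 2b²fθ²): the second derivative of the Gaussian transverse to
      the major axis.  Its transverse DC gain is zero, so it responds to
      elongated ridges along θ but not to locally flat energy — a ridge
      detector.  Normalised to unit absolute sum (its signed sum vanishes).
    """
    if not (0 <= theta < 180):
        raise ConfigError("theta must lie in [0, 180)")
    if kind not in ("smooth", "ridge"):
        raise ConfigError(f"unknown kernel kind {kind!r}")
    return _kernel_cached(float(theta), params, kind)


@lru_cache(maxsize=512)
def _kernel_cached(theta: float, params: KernelParams, kind: str) -> np.ndarray:
    hw = params.support_halfwidth
    t = np.arange(-hw, hw + 1)[:, None]  # time offset (rows)
    f = np.arange(-hw, hw + 1)[None, :]  # frequency offset (cols)
    rad = np.deg2rad(theta)
    t_th = t * np.cos(rad) + f * np.sin(rad)
    f_th = f * np.cos(rad) - t * np.sin(rad)
    g = (
        params.a
        * params.b
        / (2.0 * np.pi)
        * np.exp(-(params.a**2) * t_th**2 - (params.b**2) * f_th**2)
    )
    if kind == "ridge":
        g = g * (1.0 - 2.0 * params.b**2 * f_th**2)
        g = g - g.mean()  # exactly zero DC on the discrete grid
        g = g / np.abs(g).sum()
    else:
        if params.second_derivative:
            g = g * (1.0 - params.a**2 * t_th**2)
        g = g / g.sum()
    g.setflags(write=False)
    return g


def _padded_shape(shape: tuple[int, int], hw: int) -> tuple[int, int]:
    return (
        scipy.fft.next_fast_len(shape[0] + 2 * hw),
        scipy.fft.next_fast_len(shape[1] + 2 * hw),
    )


@lru_cache(maxsize=16)
def _kernel_ffts(
    shape: tuple[int, int], params: KernelParams, kind: str
) -> tuple[np.ndarray, ...]:
    """rfft2 of every grid-angle kernel, zero-padded for 'same' convolution."""
    pad = _padded_shape(shape, params.support_halfwidth)
    out = []
    for theta in params.theta_grid:
        out.append(scipy.fft.rfft2(_kernel_cached(float(theta), params, kind), s=pad))
    return tuple(out)


def _convolve_same(
    mat: np.ndarray, params: KernelParams, angle_idx, kind: str = "smooth"
) -> np.ndarray:
    """2-D 'same' convolution of ``mat`` with the kernels at ``angle_idx``.

    Returns an array of shape (len(angle_idx), *mat.shape).  The input FFT is
    computed once and reused across angles.
    """
    hw = params.support_halfwidth
    pad = _padded_shape(mat.shape, hw)
    mat_fft = scipy.fft.rfft2(mat, s=pad)
    kffts = _kernel_ffts(mat.shape, params, kind)
    out = np.empty((len(angle_idx), *mat.shape))
    for j, ai in enumerate(angle_idx):
        full = scipy.fft.irfft2(mat_fft * kffts[ai], s=pad)
        out[j] = full[hw : hw + mat.shape[0], hw : hw + mat.shape[1]]
    return out


def direction_map(
    tfd: TimeFrequencyDistribution, params: KernelParams
) -> DirectionMap:
    """Estimate the local ridge orientation at every TF point.

    For each angle on the quantised grid, |tfd| is convolved with the
    directional ridge-detector filter; the angle whose response magnitude
    is largest wins, ties (within 1e-9 relative) going to the smallest
    angle.  Points whose best response is negligible relative to the
    global maximum (flat regions — the zero-DC detector returns ~0 there)
    fall back to the smallest grid angle.
    """
    grid = params.theta_grid
    src = np.abs(tfd.values)
    resp = np.abs(_convolve_same(src, params, range(grid.size), kind="ridge"))
    rmax = resp.max(axis=0)
    gmax = resp.max()
    floor = _TIE_RTOL * gmax
    tol = np.maximum(_TIE_RTOL * rmax, floor)
    # first (smallest-angle) index within tolerance of the maximum
    idx = np.argmax(resp >= (rmax - tol)[None, :, :], axis=0)
    idx[rmax <= floor] = 0
    return DirectionMap(grid[idx], grid)


def adtfd(
    tfd: TimeFrequencyDistribution,
    dmap: DirectionMap,
    params: KernelParams,
) -> TimeFrequencyDistribution:
    """Adaptive directional smoothing of a TFD.

    Output(t,f) is the 2-D convolution of the input with the kernel oriented
    at θ(t,f), evaluated at (t,f): one smoothed copy per angle actually
    present in the map is computed and the per-point value selected.
    """
    if dmap.values.shape != tfd.values.shape:
        raise InvalidInputError("direction map shape must match TFD shape")
    grid = params.theta_grid
    idx_map = np.searchsorted(grid, dmap.values)
    used = np.unique(idx_map)
    smoothed = _convolve_same(tfd.values, params, used)
    pos = np.searchsorted(used, idx_map)
    out = np.take_along_axis(smoothed, pos[None, :, :], axis=0)[0]
    return TimeFrequencyDistribution(out, tfd.time_axis, tfd.freq_axis, tfd.rate)


def compute_adtfd(
    x: SampledSignal, params: KernelParams | None = None
) -> tuple[TimeFrequencyDistribution, DirectionMap]:
    """Full chain: analytic signal → WVD → orientation map → ADTFD.

    The orientation map steering the adaptive smoothing is estimated from
    the WVD; the returned map (used for downstream ridge gating) is
    re-estimated on the smoothed distribution ρ itself.
    """
    if params is None:
        params = KernelParams()
    if params.lag_window_len is not None and x.samples.size < params.lag_window_len:
        raise InvalidInputError("signal shorter than the lag window")
    z = analytic_signal(x)
    w = wvd(z, x.rate, params.lag_window_len)
    dmap0 = direction_map(w, params)
    rho = adtfd(w, dmap0, params)
    dmap = direction_map(rho, params)
    return rho, dmap
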