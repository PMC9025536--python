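"""The 18-feature set for one 8-s EEG segment.

* T1-T4 — energies of the modified time marginal s(t) over the four 2-s
  quarters of the segment (spike-train signature).
* F1-F6 — energies of the modified frequency marginal s(f) over the bands
  [0,1), [1,2), [2,3), [3,4), [4,8), [8,16] Hz (chirp/tone signature; most
  neonatal seizure energy sits below 4 Hz).
* TF1-TF8 — statistics of the orientation-filtered distribution ρFIL:
  mean, standard deviation, coefficient of variation, skewness, kurtosis,
  spectral flatness, energy-concentration measure Σ|ρ|^(1/2)ΔtΔf, and the
  TF flux Σ|Δt Δf ρ| ΔtΔf (integrated mixed first difference).

TF1-TF6 are sample statistics of the multiset of ρFIL values; flatness is
the geometric/arithmetic mean ratio of |ρFIL| (floored at 1e-12) so a
uniform distribution scores exactly 1.  TF7 and TF8 are integrals, with
absolute values inside the fractional power and the flux (the TFD may be
locally negative).  Features are never amplitude-normalised: for a
quadratic TFD, scaling the signal by c scales T, F, TF1 and TF2 by c² while
TF3-TF6 are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .ridges import (
    GatedTFD,
    Marginal,
    filtered_tfd,
    frequency_marginal,
    select_freq_axis_ridges,
    select_time_axis_ridges,
    time_marginal,
)
from .tfd import ConfigError, InvalidInputError, KernelParams, SampledSignal, compute_adtfd

__all__ = [
    "FEATURE_NAMES",
    "FREQ_BANDS_HZ",
    "FeatureVector",
    "time_marginal_features",
    "frequency_marginal_features",
    "tf_statistical_features",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    "T1", "T2", "T3", "T4",
    "F1", "F2", "F3", "F4", "F5", "F6",
    "TF1", "TF2", "TF3", "TF4", "TF5", "TF6", "TF7", "TF8",
)

FREQ_BANDS_HZ: tuple[tuple[float, float], ...] = (
    (0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 8.0), (8.0, 16.0),
)

_FLATNESS_FLOOR = 1e-12


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 18-tuple (T1..T4, F1..F6, TF1..TF8) for one segment."""

    values: np.ndarray
    degenerate: bool = False  # ρFIL was all-zero; ratio features returned as 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (18,):
            raise InvalidInputError("feature vector must have length 18")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def time_marginal_features(
    s: Marginal, segment_duration: float = 8.0
) -> tuple[float, float, float, float]:
    """Energies of s(t) over the four equal quarters of the segment.

    T_{k+1} = ∫_{2k}^{2(k+1)} s(t) dt for k = 0..3 on the default 8-s
    segment; the quarters partition the segment so ΣT equals the total
    integral exactly.
    """
    if s.kind != "time":
        raise InvalidInputError("expected a time marginal")
    t = s.axis - s.axis[0]
    n = s.values.size
    if not np.isclose(n * s.bin_width, segment_duration, rtol=1e-6):
        raise ConfigError(
            f"marginal spans {n * s.bin_width:g} s, expected {segment_duration:g} s"
        )
    edges = np.linspace(0.0, segment_duration, 5)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (t >= lo) & (t < hi)
        out.append(float(s.values[mask].sum() * s.bin_width))
    return tuple(out)


def frequency_marginal_features(s: Marginal) -> tuple[float, ...]:
    """Band energies F1..F6 of s(f) over [0,1), ..., [4,8), [8,16] Hz."""
    if s.kind != "frequency":
        raise InvalidInputError("expected a frequency marginal")
    if s.axis[-1] + s.bin_width < 16.0 - 1e-9:
        raise ConfigError("frequency axis must reach 16 Hz (rate 32 Hz)")
    out = []
    for i, (lo, hi) in enumerate(FREQ_BANDS_HZ):
        if i == len(FREQ_BANDS_HZ) - 1:
            mask = (s.axis >= lo) & (s.axis <= hi)
        else:
            mask = (s.axis >= lo) & (s.axis < hi)
        out.append(float(s.values[mask].sum() * s.bin_width))
    return tuple(out)


def tf_statistical_features(rho_fil: GatedTFD) -> tuple[float, ...]:
    """TF1..TF8 statistics of the orientation-filtered distribution.

    Returns (mean, std, coeff-of-variation, skewness, kurtosis, flatness,
    energy concentration, flux).  If the mean is zero (degenerate segment),
    the ratio features TF3 and TF6 are returned as 0.
    """
    v = np.asarray(rho_fil.values, dtype=float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise InvalidInputError("TFD must be non-empty and finite")
    flat = v.ravel()
    tf1 = float(flat.mean())
    tf2 = float(flat.std())
    tf3 = float(tf2 / tf1) if tf1 != 0.0 else 0.0
    if tf2 == 0.0:
        tf4 = 0.0
        tf5 = 0.0
    else:
        tf4 = float(scipy.stats.skew(flat))
        tf5 = float(scipy.stats.kurtosis(flat, fisher=False))
    absv = np.abs(flat)
    amean = absv.mean()
    if amean == 0.0:
        tf6 = 0.0
    else:
        # floor relative to the peak magnitude: a gated TFD is mostly exact
        # zeros, and a relative floor keeps flatness scale-invariant
        floor = _FLATNESS_FLOOR * absv.max()
        gmean = float(np.exp(np.mean(np.log(np.maximum(absv, floor)))))
        tf6 = gmean / amean
    cell = rho_fil.dt * rho_fil.df
    tf7 = float(np.sqrt(absv).sum() * cell)
    mixed = np.diff(np.diff(v, axis=0), axis=1)
    tf8 = float(np.abs(mixed).sum() * cell)
    return (tf1, tf2, tf3, tf4, tf5, tf6, tf7, tf8)


def extract_features(
    x: SampledSignal, params: KernelParams | None = None
) -> FeatureVector:
    """Full feature chain for one 8-s, 32 Hz segment (256 samples).

    ADTFD → orientation gating → modified marginals → (T1..T4, F1..F6,
    TF1..TF8).  Deterministic for a fixed input and kernel configuration.
    """
    if x.rate != 32.0:
        raise ConfigError("segments must be sampled at 32 Hz")
    if x.samples.size != 256:
        raise ConfigError("segments must contain 256 samples (8 s at 32 Hz)")
    rho, dmap = compute_adtfd(x, params)
    rho_t = select_freq_axis_ridges(rho, dmap)
    rho_f = select_time_axis_ridges(rho, dmap)
    rho_fil = filtered_tfd(rho_t, rho_f)
    t_feats = time_marginal_features(time_marginal(rho_t))
    f_feats = frequency_marginal_features(frequency_marginal(rho_f))
    tf_feats = tf_statistical_features(rho_fil)
    values = np.array(t_feats + f_feats + tf_feats)
    degenerate = not np.any(rho_fil.values)
    return FeatureVector(values, degenerate=degenerate)
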