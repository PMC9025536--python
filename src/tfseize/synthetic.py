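"""Seeded synthetic neonatal-EEG generator.

Seizure epochs follow the two canonical morphologies: a train of impulses
x(t) = Σ δ(t - tn) (rhythmic spiking), or a sum of harmonically related
frequency-modulated chirps whose fundamental instantaneous frequency f0(t)
is a slowly varying piecewise-linear curve below ~4 Hz, realised
phase-continuously as Σ_n cos(2π n ∫f0).  Background epochs are broadband
noise (white or power-law), whose TF ridges point in random directions.
Multi-patient recordings mix a seizure waveform into every channel with
per-channel gains on top of independent background noise, and carry the
ground-truth seizure intervals as annotations.

The generator targets the geometry the detector exploits (axis-aligned vs
randomly oriented TF ridges), not full neonatal EEG morphology: no burst
suppression, no artifacts, no inter-channel propagation delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate

from .pipeline import EEGRecording
from .tfd import ConfigError, InvalidInputError, SampledSignal

__all__ = [
    "SeizureSpec",
    "BackgroundSpec",
    "gen_spike_train",
    "gen_chirp_sum",
    "gen_background",
    "gen_recording",
    "default_patient_specs",
]

#: default background noise std (µV), a typical neonatal EEG background scale
BACKGROUND_SIGMA_UV = 15.0
#: default spike amplitude (µV) — sharp transients well above background
SPIKE_AMPLITUDE_UV = 300.0
#: default per-harmonic chirp amplitude (µV)
CHIRP_AMPLITUDE_UV = 60.0


@dataclass(frozen=True)
class SeizureSpec:
    """One seizure event inside a recording.

    ``kind`` is "spike_train" (impulses at ``spike_times``, seconds) or
    "chirp_sum" (``f0_breakpoints`` as (time_s, hz) pairs defining the
    piecewise-linear fundamental IF, summed over ``n_harmonics``).
    """

    kind: str
    interval: tuple[float, float]
    amplitude: float
    spike_times: tuple[float, ...] = ()
    f0_breakpoints: tuple[tuple[float, float], ...] = ()
    n_harmonics: int = 1

    def __post_init__(self):
        if self.kind not in ("spike_train", "chirp_sum"):
            raise ConfigError(f"unknown seizure kind {self.kind!r}")
        if self.interval[0] >= self.interval[1]:
            raise InvalidInputError("seizure interval must have positive length")
        if self.n_harmonics < 1:
            raise ConfigError("need at least one harmonic")
        if self.kind == "spike_train":
            for t in self.spike_times:
                if not (self.interval[0] <= t < self.interval[1]):
                    raise InvalidInputError("spike time outside the seizure interval")
        else:
            freqs = [f for _, f in self.f0_breakpoints]
            if not freqs or min(freqs) <= 0 or max(freqs) >= 16.0:
                raise InvalidInputError("fundamental IF must stay inside (0, 16) Hz")


@dataclass(frozen=True)
class BackgroundSpec:
    """Background noise model: white, or power-law with spectrum ∝ f^-exponent."""

    model: str = "white"
    amplitude: float = BACKGROUND_SIGMA_UV
    exponent: float = 1.0

    def __post_init__(self):
        if self.model not in ("white", "powerlaw"):
            raise ConfigError(f"unknown background model {self.model!r}")
        if self.amplitude < 0:
            raise InvalidInputError("amplitude must be non-negative")


def gen_spike_train(
    spec: SeizureSpec, rate: float, duration: float, smooth: bool = False
) -> SampledSignal:
    """Train of single-sample impulses at the samples nearest each spike time.

    With ``smooth`` each impulse is spread over two samples (a discrete
    stand-in for a band-limited spike).
    """
    if spec.kind != "spike_train":
        raise InvalidInputError("spec.kind must be 'spike_train'")
    n = int(round(duration * rate))
    x = np.zeros(n)
    for t in spec.spike_times:
        idx = int(round(t * rate))
        if not (0 <= idx < n):
            raise InvalidInputError(f"spike at {t} s falls outside the record")
        x[idx] += spec.amplitude
        if smooth and idx + 1 < n:
            x[idx] *= 0.5
            x[idx + 1] += 0.5 * spec.amplitude
    return SampledSignal(x, rate)


def _f0_curve(spec: SeizureSpec, t: np.ndarray) -> np.ndarray:
    pts = sorted(spec.f0_breakpoints)
    tp = np.array([p[0] for p in pts])
    fp = np.array([p[1] for p in pts])
    return np.interp(t, tp, fp)


def gen_chirp_sum(spec: SeizureSpec, rate: float, duration: float) -> SampledSignal:
    """Sum of harmonically related FM chirps, Σ_n cos(2π n φ(t)).

    φ(t) is the running integral of the piecewise-linear fundamental IF, so
    the phase is continuous across breakpoints.
    """
    if spec.kind != "chirp_sum":
        raise InvalidInputError("spec.kind must be 'chirp_sum'")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f0 = _f0_curve(spec, t)
    if spec.n_harmonics * f0.max() >= rate / 2.0:
        raise ConfigError("highest harmonic would alias at this sampling rate")
    phase = scipy.integrate.cumulative_trapezoid(f0, t, initial=0.0)
    x = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        x += np.cos(2.0 * np.pi * k * phase)
    return SampledSignal(spec.amplitude * x, rate)


def gen_background(
    spec: BackgroundSpec, rate: float, duration: float, seed: int
) -> SampledSignal:
    """Seeded background noise with the requested spectral shape and std."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = rng.standard_normal(n)
    if spec.model == "powerlaw":
        spec_x = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, d=1.0 / rate)
        shaping = np.ones_like(f)
        shaping[1:] = f[1:] ** (-spec.exponent / 2.0)
        shaping[0] = 0.0
        x = np.fft.irfft(spec_x * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return SampledSignal(spec.amplitude * x, rate)


def _seizure_waveform(spec: SeizureSpec, rate: float, duration: float) -> np.ndarray:
    """Full-record waveform with the seizure confined to its interval."""
    if spec.kind == "spike_train":
        wave = gen_spike_train(spec, rate, duration).samples
    else:
        wave = gen_chirp_sum(spec, rate, duration).samples
        n = wave.size
        t = np.arange(n) / rate
        mask = (t >= spec.interval[0]) & (t < spec.interval[1])
        wave = wave * mask
    return wave


def default_patient_specs(
    n_patients: int,
    duration: float,
    seed: int,
    seizure_duration: float = 96.0,
) -> list[list[SeizureSpec]]:
    """One seizure per patient, alternating spike-train and chirp-sum kinds.

    Spike trains are rhythmic at ~1.5 Hz with jitter; chirp fundamentals
    wander slowly inside [1, 3] Hz with two harmonics — both within the
    sub-4-Hz band where most neonatal seizure energy lives.  The default
    96-s seizure is in the minutes-scale range typical of neonatal events;
    onsets are snapped to the 8-s segmentation grid so the ground-truth
    labels are unambiguous.
    """
    rng = np.random.default_rng(seed)
    seizure_duration = min(seizure_duration, 8.0 * ((duration / 2.5) // 8.0))
    hi = duration - seizure_duration - 8.0
    lo = min(0.1 * duration, 0.5 * hi)
    if hi <= 0:
        raise InvalidInputError("record too short for a seizure plus margins")
    out = []
    for p in range(n_patients):
        start = 8.0 * round(float(rng.uniform(lo, hi)) / 8.0)
        interval = (start, start + seizure_duration)
        if p % 2 == 0:
            period = 1.0 / 1.5
            times = np.arange(interval[0] + 0.2, interval[1] - 0.1, period)
            times = times + rng.uniform(-0.05, 0.05, size=times.size)
            times = np.clip(times, interval[0], np.nextafter(interval[1], 0))
            spec = SeizureSpec(
                kind="spike_train",
                interval=interval,
                amplitude=SPIKE_AMPLITUDE_UV,
                spike_times=tuple(float(t) for t in times),
            )
        else:
            n_bp = 5
            bp_t = np.linspace(interval[0], interval[1], n_bp)
            bp_f = rng.uniform(1.0, 3.0, size=n_bp)
            # cap the IF slope so harmonics stay within the time-ridge gate
            for i in range(1, n_bp):
                df_max = 0.04 * (bp_t[i] - bp_t[i - 1])
                bp_f[i] = np.clip(bp_f[i], bp_f[i - 1] - df_max, bp_f[i - 1] + df_max)
            spec = SeizureSpec(
                kind="chirp_sum",
                interval=interval,
                amplitude=CHIRP_AMPLITUDE_UV,
                f0_breakpoints=tuple(
                    (float(t), float(f)) for t, f in zip(bp_t, bp_f)
                ),
                n_harmonics=2,
            )
        out.append([spec])
    return out


def gen_recording(
    n_patients: int = 6,
    duration: float = 200.0,
    n_channels: int = 8,
    rate: float = 32.0,
    seed: int = 0,
    seizure_specs: list[list[SeizureSpec]] | None = None,
    background: BackgroundSpec | None = None,
) -> list[EEGRecording]:
    """Generate a multi-patient dataset with labelled seizure intervals.

    Each patient gets one multi-channel record: the seizure waveform is
    mixed into every channel with a per-channel gain drawn near 1, on top of
    channel-independent background noise.  Fully reproducible from ``seed``.
    """
    if n_patients < 1:
        raise InvalidInputError("need at least one patient")
    if background is None:
        background = BackgroundSpec()
    if seizure_specs is None:
        seizure_specs = default_patient_specs(n_patients, duration, seed)
    if len(seizure_specs) != n_patients:
        raise InvalidInputError("one seizure-spec list per patient required")
    records = []
    master = np.random.default_rng(seed)
    for p, specs in enumerate(seizure_specs):
        intervals = sorted(s.interval for s in specs)
        for (a0, b0), (a1, _b1) in zip(intervals, intervals[1:]):
            if a1 < b0:
                raise InvalidInputError("seizure intervals overlap")
        pid = f"sim{p:02d}"
        chan_seed = master.integers(0, 2**31 - 1)
        rng = np.random.default_rng(chan_seed)
        n = int(round(duration * rate))
        wave = np.zeros(n)
        for s in specs:
            wave += _seizure_waveform(s, rate, duration)
        channels = np.empty((n_channels, n))
        for c in range(n_channels):
            bg = gen_background(
                background, rate, duration, seed=int(rng.integers(0, 2**31 - 1))
            )
            gain = rng.uniform(0.8, 1.2)
            channels[c] = bg.samples + gain * wave
        labels = [f"C{c + 1}" for c in range(n_channels)]
        annotations = [(s.interval[0], s.interval[1], "seizure") for s in specs]
        records.append(
            EEGRecording(
                channels=channels,
                rate=rate,
                channel_labels=labels,
                patient_id=pid,
                annotations=annotations,
            )
        )
    return records
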