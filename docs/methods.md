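# Methods

## Discrete Wigner–Ville distribution

The analytic associate z(n) is computed with the FFT-based Hilbert
transform. The pseudo-WVD uses the instantaneous autocorrelation over
half-lags, `K(n, m) = z(n+m) z*(n−m)`, truncated to an odd lag window
(default: the full odd-truncated segment length, 255 lags for a 256-sample
segment) and zero outside the record, Fourier-transformed over m. Frequency
bin k maps to `k·fs/(2·nbins)` Hz: the discrete WVD of an analytic signal
is periodic in frequency with period fs/2, so the axis is the half-open
band [0, fs/2) with uniform bin width Δf = (fs/2)/nbins; an inclusive
endpoint bin would duplicate DC. The 2/fs scaling makes the time-marginal
identity `Σ_k W(n,k)·Δf = |z(n)|²` hold exactly at every time sample
(only the m = 0 lag contributes to the sum over bins). K is Hermitian in m
even under edge truncation, so the transform is real up to rounding; the
imaginary residue is checked against 1e-8 of total energy before being
discarded.

## Directional kernels

Two filters share the rotated coordinates `tθ = t·cosθ + f·sinθ`,
`fθ = f·cosθ − t·sinθ` and the envelope `(ab/2π)·exp(−a²tθ² − b²fθ²)`,
evaluated on the integer grid with support half-width 36 points
(3 major-axis standard deviations):

* **Smoothing kernel** (adaptive smoothing of W): envelope ×
  `(1 − a²tθ²)`, normalised to unit signed sum. Unit DC gain makes the
  point-wise adaptive smoothing energy-preserving on interior regions, and
  a constant input is reproduced exactly. The quadratic factor can be
  disabled (`second_derivative=False`) for a pure-Gaussian ablation.
* **Ridge detector** (direction estimation): envelope ×
  `(1 − 2b²fθ²)` — the second derivative of the Gaussian *transverse* to
  the major axis — mean-subtracted to exactly zero DC on the discrete
  grid, normalised to unit absolute sum. A ridge detector must integrate
  along the candidate ridge direction and differentiate across it; zero DC
  means locally flat energy produces no response, so an off-ridge point
  does not "see" a strong nearby ridge through a perpendicular kernel.
  With a plain smoothing kernel used for orientation estimation instead,
  the estimated field near a ridge points perpendicular to it and the
  downstream gates leak: measured union-gate energy fractions drop from
  0.74/0.73 (spike train / chirp) to 0.35/0.54, below what the gating
  step needs. This choice is the single most load-bearing numerical
  decision in the package.

Defaults `a = 1/(12√2)`, `b = 1/(2√2)` give a 12-point standard deviation
along the ridge and 2 points across it on the 256×256 segment grid —
long enough along time to average out the fastest in-band cross-term
oscillation (4 Hz beat ≈ 8 samples), narrow enough across frequency to
preserve 1-bin ridges. Angles are quantised to θ ∈ {0°, 3°, …, 177°}
(180° ≡ 0°); ties in the argmax go to the smallest angle, with responses
within 1e-9 relative treated as tied. Points whose best response is below
1e-9 of the global maximum (flat regions) also fall back to 0°.

The orientation map that steers the adaptive smoothing is estimated from
|W|; the map used for downstream gating is re-estimated from the smoothed
ρ itself. One smoothing pass is applied — no fixed-point iteration. All
per-angle convolutions are FFT-based with one forward transform of the
input shared across the 60 angles, and only angles actually present in the
orientation map are smoothed.

## Gating and marginals

The spike gate (80° < θ < 100°) and the tone/chirp gate (θ < 10° or
θ > 170°) are strict inequalities; on the 3° grid the passing angle sets
are {81, 84, …, 99} and {0, 3, 6, 9, 171, 174, 177}, so boundary angles
never arise. The two gates are disjoint by construction, hence
ρFIL = ρt + ρf takes each point's value from ρ or is zero. Marginals are
Riemann sums (Δt = 1/fs, Δf = (fs/2)/nbins) of the *signed* gated
distribution — a quadratic TFD is locally negative and the marginals
integrate it as-is; ratio-style diagnostics (energy retention, test
assertions) use absolute values.

## Features

The published feature table conflates integrals with moments (the "mean"
is written as a total integral yet centres the variance; the flatness
product lacks a root; the fractional power and product are undefined for
negative values). TF1–TF6 are therefore implemented as sample statistics
of the multiset of ρFIL values — mean, standard deviation, coefficient of
variation, standardized skewness, standardized (Pearson) kurtosis, and
spectral flatness (geometric/arithmetic mean of |ρFIL|) — while TF7
(energy concentration, Σ|ρFIL|^(1/2)·ΔtΔf) and TF8 (flux,
Σ|Δt Δf ρFIL|·ΔtΔf with a mixed first-difference stencil) remain
integrals. The flatness floor is relative (1e-12 × the peak magnitude):
a gated TFD is mostly exact zeros, and a relative floor keeps TF6
scale-invariant while a uniform distribution still scores exactly 1.
When ρFIL is identically zero the ratio features TF3 and TF6 are
returned as 0 and the vector is flagged degenerate.

No per-segment amplitude normalisation is applied: amplitude is
discriminative for seizures. Scaling the input by c scales T1–T4, F1–F6,
TF1, TF2 by c² and TF7 by c, and leaves TF3–TF6 invariant.

All six frequency bands are implemented (18 features total); the band
edges treat [8, 16] as closed at the top so the six bands partition the
analysis band exactly.

## Detection pipeline

Channels are averaged first (one analysis signal per recording), then the
signal is low-pass filtered (zero-phase FIR, cutoff 0.8 × the 16 Hz
analysis Nyquist, 16·q+1 taps for decimation factor q) and decimated to
32 Hz, then differenced (x(n) − x(n−1), first output sample 0). Decimating
before differencing keeps the differentiator acting as a high-pass at the
analysis rate. Segments are non-overlapping 256-sample windows; a segment
is labelled seizure when more than half of its 8 s overlaps an annotated
interval.

Training folds are balanced by seeded random undersampling of the majority
class. The classifier is a 500-tree random forest; feature importance is
reported as permutation importance (mean accuracy drop). Cross-validation
is leave-one-patient-out with per-fold seeds keyed by a CRC of the patient
id, and segments sorted canonically by (patient, start time), so fold
composition and metrics are invariant to input order. Each test patient's
decision sequence is median-filtered (5-tap, ≥3 votes, edge replication)
and every detected run is then dilated by one segment (8 s) per side.
Metrics are pooled over all test segments of all folds; per-patient
confusion metrics are also returned. Metrics with zero denominators are
reported as 0 and flagged.

The boundary extension is applied to the *detected* mask. Against
crisp synthetic ground truth it converts exactly two segments per detected
run into false positives; it exists to recover annotated boundary segments
that the median filter trims on real data, where seizure onsets are not
aligned to the segmentation grid.

## Synthetic study conditions

The generator's defaults define the conditions under which the package
validates itself: 6 patients, 200-s single-channel-morphology records at
32 Hz, 8 channels, one 80-s seizure per patient (onset snapped to the 8-s
grid so ground-truth labels are unambiguous), alternating morphologies —
rhythmic ~1.5 Hz spike trains (300 µV transients) and two-harmonic chirp
sums (60 µV per harmonic) whose piecewise-linear fundamental wanders in
[1, 3] Hz with slope capped at 0.04 Hz/s so that both harmonics stay
inside the time-ridge gate — on white background noise of 15 µV standard
deviation with per-channel seizure gains in [0.8, 1.2]. Records can also
be generated at 256 Hz to exercise the decimation path; the 32 Hz default
keeps the test suite and the acceptance script inside a few minutes on one
CPU (150 segments end to end, ~0.3 s of ADTFD per segment).

The seizure-length and record-length choice makes the structural cost of
boundary extension (2 false-positive segments per run, i.e. a pooled-F1
ceiling of 2S/(2S+2) for S seizure segments per patient) small relative
to the seizure mass — mirroring the minutes-scale events of the clinical
database rather than short isolated bursts.

What the generator does *not* emulate: realistic neonatal background
rhythms and burst suppression, artifacts, inter-channel propagation,
seizure morphology drift, or annotation noise. Passing the synthetic
acceptance run therefore demonstrates the correctness of the machinery
(TF analysis, gating, features, cross-validation plumbing), not clinical
performance; the published clinical benchmark requires the external
36-newborn database, which enters through the same EDF + annotation path
(`tfseize detect` / `tfseize loocv`).

## Numerical details and degenerate inputs

* WVD lag truncation near record edges shortens the effective window;
  marginal identities are asserted on interior samples.
* FFT convolution vs direct convolution can flip exact argmax ties in the
  orientation map; the tie tolerance (1e-9 relative) absorbs this.
* A constant TFD yields orientation 0° everywhere in the interior; within
  a kernel half-width of the border, zero padding produces genuine edge
  responses.
* Empty spike lists, zero-amplitude backgrounds and all-zero segments are
  valid inputs and propagate to zero features with the degenerate flag.
* The EDF writer emits 16-bit samples over a symmetric physical range of
  the channel peak; round-trip error is bounded by one quantisation step.

## Test-suite problem sizes

Brute-force WVD oracle equivalence is checked at 48–64 samples; the
direction-map oracle on a 40×40 grid with a 15° step; property fuzzing of
the TF statistics on 8×8 matrices across hypothesis-driven seeds; the
full-chain fuzz on 5 random 256-sample segments; the end-to-end detection
run on the 6-patient default dataset (150 segments). These sizes keep the
suite under two minutes on one CPU while covering every code path.
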