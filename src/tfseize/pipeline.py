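"""Segment-level seizure detection pipeline.

Multi-channel recordings are spatially averaged to one signal, low-pass
filtered and decimated to 32 Hz, passed through the first-difference
pre-whitening filter x(n) - x(n-1), and cut into non-overlapping 8-s
segments (256 samples).  Each segment yields the 18-dimensional
time-frequency feature vector; a random forest classifies segments, with
leave-one-patient-out cross-validation, class-balanced training folds
(random undersampling of the majority class), a 5-tap median filter over
the decision sequence (at least 3 of 5 votes), and an 8-s dilation of each
detected seizure run to recover the boundary segments the median filter
trims.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .tfd import ConfigError, InvalidInputError, KernelParams, SampledSignal

__all__ = [
    "EEGRecording",
    "SegmentSet",
    "DetectionResult",
    "ClassifierConfig",
    "spatial_average",
    "preprocess",
    "segment_signal",
    "label_segments",
    "extract_segment_features",
    "balance_training",
    "train_classifier",
    "predict",
    "median_smooth",
    "extend_boundaries",
    "evaluate",
    "f1_from_precision_sensitivity",
    "loocv",
]

SEGMENT_SECONDS = 8.0
ANALYSIS_RATE = 32.0
SEGMENT_SAMPLES = int(SEGMENT_SECONDS * ANALYSIS_RATE)
#: fraction of a segment that must overlap a seizure interval for label 1
LABEL_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class EEGRecording:
    """One patient's multi-channel EEG with seizure-interval annotations.

    ``annotations`` holds (start_s, end_s, "seizure") tuples, seconds from
    record start, half-open intervals.
    """

    channels: np.ndarray  # (n_channels, n_samples), µV
    rate: float
    channel_labels: list[str]
    patient_id: str
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        ch = np.asarray(self.channels, dtype=float)
        object.__setattr__(self, "channels", ch)
        if self.rate <= 0:
            raise ConfigError("sampling rate must be positive")
        if ch.ndim != 2 or ch.shape[0] < 1:
            raise InvalidInputError("channels must be a (n_channels, n_samples) matrix")
        dur = ch.shape[1] / self.rate
        for start, end, _label in self.annotations:
            if not (0 <= start < end <= dur + 1e-9):
                raise InvalidInputError(
                    f"annotation [{start}, {end}) outside record of {dur:g} s"
                )

    @property
    def duration(self) -> float:
        return self.channels.shape[1] / self.rate


@dataclass
class SegmentSet:
    """Non-overlapping 8-s, 32 Hz segments with metadata (and labels)."""

    segments: np.ndarray  # (n_segments, 256)
    patient_ids: np.ndarray  # (n_segments,) str
    start_times: np.ndarray  # (n_segments,) seconds
    labels: np.ndarray | None = None  # (n_segments,) {0,1}

    def __len__(self) -> int:
        return self.segments.shape[0]


@dataclass
class DetectionResult:
    """Per-segment decisions and confusion-matrix metrics for one evaluation."""

    raw_decisions: np.ndarray
    smoothed_decisions: np.ndarray
    extended_mask: np.ndarray
    truth: np.ndarray
    metrics: dict[str, float]
    undefined_metrics: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 500
    seed: int = 0
    kernel_params: KernelParams = field(default_factory=KernelParams)


def spatial_average(rec: EEGRecording) -> SampledSignal:
    """Arithmetic mean across channels — the single analysis signal x(t)."""
    if rec.channels.shape[0] < 1:
        raise InvalidInputError("recording has no channels")
    return SampledSignal(rec.channels.mean(axis=0), rec.rate)


def preprocess(x: SampledSignal, target_rate: float = ANALYSIS_RATE) -> SampledSignal:
    """Anti-alias low-pass, decimate to 32 Hz, then first-difference filter.

    The zero-phase FIR low-pass cuts at 0.8 of the post-decimation Nyquist
    before downsampling; the differentiator x(n) - x(n-1) (first output
    sample 0) whitens the 1/f background and sharpens spike transients.
    Output length is floor(n_in * target_rate / rate).
    """
    if x.rate % target_rate != 0:
        raise ConfigError(f"rate {x.rate:g} Hz is not a multiple of {target_rate:g} Hz")
    q = int(x.rate // target_rate)
    samples = x.samples
    if q > 1:
        cutoff = 0.8 * (target_rate / 2.0)
        ntaps = 16 * q + 1
        taps = scipy.signal.firwin(ntaps, cutoff, fs=x.rate)
        samples = scipy.signal.filtfilt(taps, [1.0], samples)
        samples = samples[::q]
    diffed = np.diff(samples, prepend=samples[:1])
    return SampledSignal(diffed, target_rate, start_time=x.start_time)


def segment_signal(x: SampledSignal, patient_id: str = "") -> SegmentSet:
    """Cut a 32 Hz signal into non-overlapping 256-sample segments."""
    if x.rate != ANALYSIS_RATE:
        raise ConfigError("segmentation expects the 32 Hz analysis rate")
    n_seg = x.samples.size // SEGMENT_SAMPLES
    if n_seg < 1:
        raise InvalidInputError("signal shorter than one 8-s segment")
    segs = x.samples[: n_seg * SEGMENT_SAMPLES].reshape(n_seg, SEGMENT_SAMPLES)
    starts = x.start_time + np.arange(n_seg) * SEGMENT_SECONDS
    return SegmentSet(
        segments=segs,
        patient_ids=np.array([patient_id] * n_seg),
        start_times=starts,
    )


def label_segments(
    segs: SegmentSet, annotations: list[tuple[float, float, str]]
) -> SegmentSet:
    """Label a segment 1 iff more than half its duration overlaps a seizure."""
    labels = np.zeros(len(segs), dtype=int)
    for i, t0 in enumerate(segs.start_times):
        t1 = t0 + SEGMENT_SECONDS
        overlap = 0.0
        for start, end, _label in annotations:
            overlap += max(0.0, min(t1, end) - max(t0, start))
        if overlap > LABEL_OVERLAP_FRACTION * SEGMENT_SECONDS:
            labels[i] = 1
    return SegmentSet(segs.segments, segs.patient_ids, segs.start_times, labels)


def extract_segment_features(
    segs: SegmentSet, params: KernelParams | None = None
) -> np.ndarray:
    """18-dimensional feature matrix, one row per segment."""
    from .features import extract_features  # deferred: features imports tfd chain

    out = np.empty((len(segs), 18))
    for i in range(len(segs)):
        fv = extract_features(SampledSignal(segs.segments[i], ANALYSIS_RATE), params)
        out[i] = fv.values
    return out


def balance_training(
    features: np.ndarray, labels: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Undersample the majority class to the minority count (seeded)."""
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    k = min(pos.size, neg.size)
    keep_pos = pos if pos.size == k else np.sort(rng.choice(pos, size=k, replace=False))
    keep_neg = neg if neg.size == k else np.sort(rng.choice(neg, size=k, replace=False))
    keep = np.sort(np.concatenate([keep_pos, keep_neg]))
    return features[keep], labels[keep]


def train_classifier(
    features: np.ndarray, labels: np.ndarray, config: ClassifierConfig | None = None
) -> RandomForestClassifier:
    """Fit the random forest on 18-dimensional feature vectors."""
    if config is None:
        config = ClassifierConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[1] != 18:
        raise InvalidInputError("features must be (n_segments, 18)")
    if features.shape[0] != labels.size:
        raise InvalidInputError("feature/label length mismatch")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    clf.fit(features, labels)
    return clf


def predict(clf: RandomForestClassifier, features: np.ndarray) -> np.ndarray:
    """Binary segment decisions."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 18:
        raise InvalidInputError("features must be (n_segments, 18)")
    return clf.predict(features).astype(int)


def feature_importance(
    clf: RandomForestClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Permutation importance: mean accuracy drop when a feature is scrambled."""
    res = permutation_importance(
        clf, features, labels, scoring="accuracy", n_repeats=10, random_state=seed
    )
    return res.importances_mean


def median_smooth(decisions: np.ndarray) -> np.ndarray:
    """5-tap median filter: a segment is a seizure iff ≥ 3 of the 5 segments
    centred on it are, with edge-replication padding."""
    d = np.asarray(decisions, dtype=int)
    if d.size == 0:
        raise InvalidInputError("empty decision sequence")
    padded = np.concatenate([d[:1], d[:1], d, d[-1:], d[-1:]])
    windows = np.lib.stride_tricks.sliding_window_view(padded, 5)
    return (windows.sum(axis=1) >= 3).astype(int)


def extend_boundaries(mask: np.ndarray) -> np.ndarray:
    """Grow every detected seizure run by one segment (8 s) on each side."""
    m = np.asarray(mask, dtype=bool)
    return scipy.ndimage.binary_dilation(m, structure=np.ones(3, dtype=bool)).astype(int)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> tuple[dict[str, float], tuple[str, ...]]:
    """Confusion-matrix metrics (fractions in [0, 1]).

    Returns the metric dict and the names of any metrics whose denominator
    was zero (reported as 0).
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise InvalidInputError("prediction/truth length mismatch")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    prec = ratio(tp, tp + fp, "precision")
    if prec + sens == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "precision": prec,
        "f1": f1,
    }
    return metrics, tuple(undefined)


def f1_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """F1 = 2·P·R / (P + R), the harmonic mean of precision and sensitivity."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _fold_seed(base_seed: int, patient_id: str) -> int:
    """Deterministic sub-seed keyed by patient id (order-independent)."""
    return (base_seed * 1000003 + zlib.crc32(patient_id.encode())) % (2**31 - 1)


def prepare_dataset(
    recordings: list[EEGRecording], params: KernelParams | None = None
) -> tuple[SegmentSet, np.ndarray]:
    """Recording list → pooled labelled SegmentSet + feature matrix."""
    seg_list, feat_list = [], []
    for rec in recordings:
        x = spatial_average(rec)
        x = preprocess(x)
        segs = segment_signal(x, rec.patient_id)
        segs = label_segments(segs, rec.annotations)
        seg_list.append(segs)
        feat_list.append(extract_segment_features(segs, params))
    pooled = SegmentSet(
        segments=np.concatenate([s.segments for s in seg_list]),
        patient_ids=np.concatenate([s.patient_ids for s in seg_list]),
        start_times=np.concatenate([s.start_times for s in seg_list]),
        labels=np.concatenate([s.labels for s in seg_list]),
    )
    return pooled, np.concatenate(feat_list)


def loocv(
    segs: SegmentSet,
    features: np.ndarray,
    config: ClassifierConfig | None = None,
) -> tuple[dict[str, DetectionResult], dict[str, float]]:
    """Leave-one-patient-out cross-validation.

    Each patient is the test set exactly once; the training fold never
    contains the test patient, is class-balanced by seeded undersampling,
    and the test patient's decision sequence is median-smoothed and
    boundary-extended before metrics.  Pooled metrics are computed over all
    test segments of all folds.  Per-fold seeds are keyed by patient id so
    shuffling patient order cannot change the result.
    """
    if config is None:
        config = ClassifierConfig()
    patients = sorted(set(segs.patient_ids))
    if len(patients) < 2:
        raise InvalidInputError("leave-one-patient-out needs at least 2 patients")
    # canonical ordering makes fold composition independent of input order
    order = np.lexsort((segs.start_times, segs.patient_ids))
    feats = features[order]
    labels = segs.labels[order]
    pids = segs.patient_ids[order]
    starts = segs.start_times[order]

    per_patient: dict[str, DetectionResult] = {}
    all_pred, all_truth = [], []
    for pid in patients:
        test_mask = pids == pid
        train_mask = ~test_mask
        assert not np.any(pids[train_mask] == pid)
        fs = _fold_seed(config.seed, pid)
        bal_X, bal_y = balance_training(feats[train_mask], labels[train_mask], fs)
        fold_cfg = ClassifierConfig(
            n_trees=config.n_trees, seed=fs, kernel_params=config.kernel_params
        )
        clf = train_classifier(bal_X, bal_y, fold_cfg)
        # test segments in temporal order for the decision-sequence filters
        t_order = np.argsort(starts[test_mask])
        raw = predict(clf, feats[test_mask][t_order])
        smoothed = median_smooth(raw)
        extended = extend_boundaries(smoothed)
        truth = labels[test_mask][t_order]
        metrics, undef = evaluate(extended, truth)
        per_patient[pid] = DetectionResult(
            raw_decisions=raw,
            smoothed_decisions=smoothed,
            extended_mask=extended,
            truth=truth,
            metrics=metrics,
            undefined_metrics=undef,
        )
        all_pred.append(extended)
        all_truth.append(truth)
    pooled, _ = evaluate(np.concatenate(all_pred), np.concatenate(all_truth))
    return per_patient, pooled
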