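"""Readers and writers for the formats the pipeline touches.

EDF (European Data Format) is the canonical EEG container: reading goes
through :mod:`mne`, writing through a minimal 16-bit EDF writer (1-s data
records, physical units µV).  A delimited-text recording format (CSV with
``# key=value`` metadata lines) provides a zero-dependency fallback that
round-trips exactly.  Annotations, feature tables and predictions are plain
CSV with header rows.  Time is seconds from record start, 0-based,
half-open intervals [start, end).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .pipeline import DetectionResult, EEGRecording, SegmentSet
from .tfd import InvalidInputError, TimeFrequencyDistribution

__all__ = [
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "write_features",
    "read_features",
    "write_predictions",
    "read_predictions",
    "save_tfd",
    "load_tfd",
]


class ParseError(ValueError):
    """Raised when a file does not conform to its schema."""


# ---------------------------------------------------------------------------
# recordings

def read_recording(
    path: str | Path,
    fmt: str | None = None,
    patient_id: str | None = None,
    annotations: list[tuple[float, float, str]] | None = None,
) -> EEGRecording:
    """Read an EEG recording from EDF or delimited text.

    ``fmt`` is "edf" or "csv"; by default it is inferred from the suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        return _read_edf(path, patient_id, annotations or [])
    return _read_csv_recording(path, patient_id, annotations or [])


def _read_edf(path, patient_id, annotations) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise ParseError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    return EEGRecording(
        channels=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        patient_id=patient_id or path.stem,
        annotations=annotations,
    )


def _read_csv_recording(path, patient_id, annotations) -> EEGRecording:
    meta = {}
    header_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    if "rate_hz" not in meta:
        raise ParseError(f"{path}: missing '# rate_hz=' metadata line")
    try:
        rate = float(meta["rate_hz"])
    except ValueError as exc:
        raise ParseError(f"{path}: rate_hz is not numeric") from exc
    df = pd.read_csv(path, skiprows=header_lines)
    if df.shape[1] < 1 or df.shape[0] < 2:
        raise ParseError(f"{path}: expected a header row and >= 2 sample rows")
    return EEGRecording(
        channels=df.to_numpy(dtype=float).T,
        rate=rate,
        channel_labels=list(df.columns),
        patient_id=patient_id or meta.get("patient_id", path.stem),
        annotations=annotations,
    )


def write_recording(rec: EEGRecording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording as EDF (16-bit) or delimited text."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# rate_hz={rec.rate:g}\n")
            fh.write(f"# patient_id={rec.patient_id}\n")
            fh.write(",".join(rec.channel_labels) + "\n")
            np.savetxt(fh, rec.channels.T, fmt="%.10g", delimiter=",")
    return path


def _edf_field(value, width) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, int16 samples.

    The record is truncated to whole seconds and the sampling rate must be
    an integer (both hold for the formats this pipeline produces).
    """
    rate = int(rec.rate)
    if rate != rec.rate:
        raise InvalidInputError("EDF writer requires an integer sampling rate")
    ns = rec.channels.shape[0]
    n_records = rec.channels.shape[1] // rate
    if n_records < 1:
        raise InvalidInputError("recording shorter than one EDF data record (1 s)")
    data = rec.channels[:, : n_records * rate]
    phys_max = max(1.0, float(np.abs(data).max()))
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(rec.patient_id, 80),
            _edf_field("tfseize synthetic", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + ns), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    labels = [lab[:16] for lab in rec.channel_labels]
    sig_header = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in labels),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{-phys_max:.6g}"[:8], 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_max:.6g}"[:8], 8) for _ in range(ns)),
            b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
            b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(rate, 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * rate : (r + 1) * rate]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# annotations

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Seizure-interval table with columns patient_id, start_s, end_s."""
    df = pd.read_csv(path)
    required = {"patient_id", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation header must contain {sorted(required)}")
    if (df["start_s"] < 0).any() or (df["end_s"] < 0).any():
        raise ParseError(f"{path}: annotation times must be non-negative")
    if (df["start_s"] >= df["end_s"]).any():
        raise ParseError(f"{path}: annotation intervals must satisfy start_s < end_s")
    return df[["patient_id", "start_s", "end_s"]]


def write_annotations(rows: pd.DataFrame | list[tuple], path: str | Path) -> Path:
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows, columns=["patient_id", "start_s", "end_s"])
    rows.to_csv(path, index=False)
    return Path(path)


def annotations_for(df: pd.DataFrame, patient_id: str) -> list[tuple[float, float, str]]:
    """Annotation rows of one patient as (start, end, 'seizure') tuples."""
    sub = df[df["patient_id"] == patient_id]
    return [
        (float(r.start_s), float(r.end_s), "seizure") for r in sub.itertuples()
    ]


# ---------------------------------------------------------------------------
# features and predictions

_META_COLUMNS = ("segment_id", "patient_id", "t_start", "label")


def write_features(segs: SegmentSet, features: np.ndarray, path: str | Path) -> Path:
    """Feature table: segment_id, patient_id, t_start, label, T1..TF8."""
    if features.shape != (len(segs), 18):
        raise InvalidInputError("features must be (n_segments, 18)")
    labels = segs.labels if segs.labels is not None else np.full(len(segs), -1)
    df = pd.DataFrame(features, columns=list(FEATURE_NAMES))
    df.insert(0, "segment_id", np.arange(len(segs)))
    df.insert(1, "patient_id", segs.patient_ids)
    df.insert(2, "t_start", segs.start_times)
    df.insert(3, "label", labels)
    df.to_csv(path, index=False)
    return Path(path)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = list(_META_COLUMNS) + list(FEATURE_NAMES)
    if list(df.columns) != expected:
        raise ParseError(f"{path}: feature table columns must be {expected}")
    return df


def write_predictions(
    result: DetectionResult, start_times: np.ndarray, path: str | Path,
    patient_id: str = "",
) -> Path:
    """Per-segment decision table: start time, raw/smoothed/extended decisions."""
    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "t_start": start_times,
            "raw": result.raw_decisions,
            "smoothed": result.smoothed_decisions,
            "extended": result.extended_mask,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "t_start", "raw", "smoothed", "extended"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: prediction header must contain {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# TFD container

def save_tfd(tfd: TimeFrequencyDistribution, path: str | Path) -> Path:
    """Matrix as delimited text plus a JSON sidecar holding the axes."""
    path = Path(path)
    np.savetxt(path, tfd.values, delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "rate": tfd.rate,
                "time_axis": tfd.time_axis.tolist(),
                "freq_axis": tfd.freq_axis.tolist(),
            },
            fh,
        )
    return path


def load_tfd(path: str | Path) -> TimeFrequencyDistribution:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",")
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    return TimeFrequencyDistribution(
        values, np.array(meta["time_axis"]), np.array(meta["freq_axis"]), meta["rate"]
    )
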