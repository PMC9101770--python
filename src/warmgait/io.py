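"""CSV readers and writers for sensor logs, annotations, features and results.

Everything is plain CSV: sensor-log files of timestamped quaternions, interval
annotation files, feature tables, prediction tables and segment files.  Times
are normalized to seconds from trial start internally.  The quaternion column
order is configurable (default ``w, x, y, z``) because vendor exports disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable, UQTSTrial

__all__ = [
    "SensorLogDialect",
    "LabelledInterval",
    "FormatError",
    "read_uqts_csv",
    "write_uqts_csv",
    "read_labels_csv",
    "write_labels_csv",
    "apply_labels",
    "read_features_csv",
    "write_features_csv",
    "write_predictions_csv",
    "read_predictions_csv",
    "write_segments_csv",
    "read_segments_csv",
]

logger = logging.getLogger(__name__)

#: Norm deviation up to which a row is renormalized rather than rejected.
RENORM_TOL = 1e-3
#: Reject the whole file if more than this fraction of rows is dropped.
MAX_REJECT_FRACTION = 0.01


class FormatError(ValueError):
    """A file does not conform to the expected dialect/schema."""


@dataclass(frozen=True)
class SensorLogDialect:
    """Column layout of a sensor-log CSV."""

    time_column: str = "elapsed_s"
    quaternion_columns: Sequence[str] = ("w", "x", "y", "z")
    time_unit: str = "seconds"  # seconds | milliseconds | epoch_ms
    delimiter: str = ","

    def __post_init__(self) -> None:
        if len(set(self.quaternion_columns)) != 4:
            raise ValueError("need four distinct quaternion columns")
        if self.time_unit not in ("seconds", "milliseconds", "epoch_ms"):
            raise ValueError(f"unknown time_unit {self.time_unit!r}")


@dataclass(frozen=True)
class LabelledInterval:
    """A half-open annotated interval [start_s, end_s) in trial time."""

    start_s: float
    end_s: float
    activity: str = ""
    walking: int = 0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("interval must have end_s > start_s")


def read_uqts_csv(
    path,
    dialect: SensorLogDialect = SensorLogDialect(),
    trial_id: str = "",
    subject_id: str = "",
) -> UQTSTrial:
    """Read a sensor-log CSV into a trial.

    Rows with non-finite components or with quaternion norm deviating from 1
    by more than 1e-3 are rejected (and counted); deviations up to 1e-3 are
    renormalized.  To preserve the uniform sampling grid, an interior
    rejected row is replaced by the previous valid sample (zero-order hold);
    leading rejected rows are dropped.  Timestamps are converted to seconds
    from the first valid sample.

    Raises
    ------
    FormatError
        On missing columns, non-monotone time, or more than 1% rejected rows.
    """
    path = Path(path)
    df = pd.read_csv(path, delimiter=dialect.delimiter, float_precision="round_trip")
    needed = [dialect.time_column, *dialect.quaternion_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    t = df[dialect.time_column].to_numpy(dtype=float)
    q = df[list(dialect.quaternion_columns)].to_numpy(dtype=float)

    finite = np.isfinite(t) & np.isfinite(q).all(axis=1)
    norms = np.linalg.norm(np.where(np.isfinite(q), q, 0.0), axis=1)
    in_tol = np.abs(norms - 1.0) <= RENORM_TOL
    keep = finite & in_tol
    n_rejected = int((~keep).sum())
    if n_rejected:
        rows = np.flatnonzero(~keep)
        logger.warning(
            "%s: rejected %d row(s) (non-finite or off the unit sphere): rows %s%s",
            path,
            n_rejected,
            rows[:10].tolist(),
            "..." if rows.size > 10 else "",
        )
    if n_rejected > MAX_REJECT_FRACTION * len(df):
        rows = np.flatnonzero(~keep)
        raise FormatError(
            f"{path}: {n_rejected}/{len(df)} rows rejected (>1%); first bad rows "
            f"{rows[:10].tolist()}"
        )
    if not keep.any():
        raise FormatError(f"{path}: no valid rows")
    first = int(np.argmax(keep))
    t, q, keep = t[first:], q[first:], keep[first:]
    if not keep.all():
        last_valid = np.maximum.accumulate(np.where(keep, np.arange(keep.size), 0))
        q = q[last_valid]

    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise FormatError(f"{path}: time column not strictly increasing at row {bad}")
    if dialect.time_unit in ("milliseconds", "epoch_ms"):
        t = t / 1000.0
    t = t - t[0]
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    return UQTSTrial(
        times=t, quaternions=q, trial_id=trial_id or path.stem, subject_id=subject_id
    )


def write_uqts_csv(path, trial: UQTSTrial, dialect: SensorLogDialect = SensorLogDialect()) -> None:
    """Write a trial in the sensor-log dialect (times in the dialect's unit)."""
    t = trial.times
    if dialect.time_unit in ("milliseconds", "epoch_ms"):
        t = t * 1000.0
    df = pd.DataFrame({dialect.time_column: t})
    for name, col in zip(dialect.quaternion_columns, trial.quaternions.T):
        df[name] = col
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.17g")


def read_labels_csv(path) -> list[LabelledInterval]:
    """Read an interval annotation CSV (`start_s,end_s,activity,walking`)."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["start_s", "end_s", "activity", "walking"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    intervals = [
        LabelledInterval(
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            activity=str(r.activity),
            walking=int(r.walking),
        )
        for r in df.itertuples()
    ]
    _check_no_overlap(intervals)
    return intervals


def write_labels_csv(path, intervals: Sequence[LabelledInterval]) -> None:
    pd.DataFrame(
        {
            "start_s": [iv.start_s for iv in intervals],
            "end_s": [iv.end_s for iv in intervals],
            "activity": [iv.activity for iv in intervals],
            "walking": [iv.walking for iv in intervals],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def _check_no_overlap(intervals: Sequence[LabelledInterval]) -> None:
    ordered = sorted(intervals, key=lambda iv: iv.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise FormatError(
                f"overlapping annotation intervals: [{a.start_s}, {a.end_s}) and "
                f"[{b.start_s}, {b.end_s})"
            )


def apply_labels(trial: UQTSTrial, intervals: Sequence[LabelledInterval]) -> UQTSTrial:
    """Assign per-sample labels by half-open interval membership [start, end).

    Samples outside all intervals get label 0.  A sample exactly on a boundary
    belongs to the interval that starts there.
    """
    _check_no_overlap(intervals)
    labels = np.zeros(trial.n_samples, dtype=int)
    for iv in intervals:
        inside = (trial.times >= iv.start_s) & (trial.times < iv.end_s)
        labels[inside] = int(iv.walking)
    return replace(trial, labels=labels)


def intervals_from_labels(trial: UQTSTrial) -> list[LabelledInterval]:
    """Run-length encode a labelled trial into half-open annotation intervals."""
    if trial.labels is None:
        raise ValueError("trial has no labels")
    labels = trial.labels
    dt = trial.dt if trial.n_samples >= 2 else 0.0
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [trial.n_samples]])
    # interval end = start time of the next run (exact contiguity); the last
    # interval extends one step past the final sample
    return [
        LabelledInterval(
            start_s=float(trial.times[s]),
            end_s=float(trial.times[e]) if e < trial.n_samples else float(trial.times[-1] + dt),
            activity="walking" if labels[s] else "non-walking",
            walking=int(labels[s]),
        )
        for s, e in zip(starts, ends)
    ]


_FEATURE_COLUMNS = ["time", "lm", "lsd", "label", "trial_id"]


def write_features_csv(path, table: FeatureTable) -> None:
    """Write a feature table with header ``time,lm,lsd,label,trial_id``."""
    df = pd.DataFrame(
        {
            "time": table.times,
            "lm": table.lm,
            "lsd": table.lsd,
            "label": table.label if table.label is not None else [""] * len(table),
            "trial_id": [table.trial_id] * len(table),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_features_csv(path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    label = None
    if df["label"].notna().all():
        label = df["label"].to_numpy(dtype=int)
    trial_id = str(df["trial_id"].iloc[0]) if len(df) else ""
    return FeatureTable(
        times=df["time"].to_numpy(dtype=float),
        lm=df["lm"].to_numpy(dtype=float),
        lsd=df["lsd"].to_numpy(dtype=float),
        label=label,
        trial_id=trial_id,
    )


def write_predictions_csv(path, table: FeatureTable, raw_pred, smoothed_pred) -> None:
    """Write per-time-point predictions (`time,lm,lsd,label,raw_pred,smoothed_pred`)."""
    df = pd.DataFrame(
        {
            "time": table.times,
            "lm": table.lm,
            "lsd": table.lsd,
            "label": table.label if table.label is not None else [""] * len(table),
            "raw_pred": np.asarray(raw_pred, dtype=int),
            "smoothed_pred": np.asarray(smoothed_pred, dtype=int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_predictions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["time", "lm", "lsd", "label", "raw_pred", "smoothed_pred"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def write_segments_csv(path, segments) -> None:
    """Write segments as ``start_s,end_s,class,n_samples`` rows."""
    pd.DataFrame(
        {
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "class": [s.cls for s in segments],
            "n_samples": [s.n_samples for s in segments],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_segments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["start_s", "end_s", "class", "n_samples"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df
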