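"""Time-point and segment-level evaluation of walking/non-walking predictions.

Two complementary views of the same predictions:

* **Time-point (classification) metrics** — each sample is scored against its
  annotated label through the usual confusion counts.  Because manual change
  points are only trustworthy to ±25 ms, every annotated change point plus the
  12 samples on each side (at 100 Hz) is masked out before counting.

* **Segment (session) metrics** — the (true, predicted) label pairs induce a
  four-class coding (TP/FP/FN/TN) per sample; maximal runs of constant class
  form a segmentation of the trial, and the confusion counts are *numbers of
  segments*, not samples.  A long spurious walking prediction then costs as
  much as a short one, which is the point: these metrics score whether whole
  activity sessions were recovered.

Undefined ratios (zero denominators) are returned as NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Segment",
    "margin_filter_mask",
    "confusion",
    "precision",
    "accuracy",
    "detection_prevalence",
    "prevalence",
    "combined_segmentation",
    "segments_from_labels",
    "segment_confusion",
    "metrics_report",
]

#: Samples masked on each side of an annotated change point (25 ms at 100 Hz).
DEFAULT_CHANGE_MARGIN = 12


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts over time points or over segments."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Segment:
    """A maximal run of constant class; indices half-open [start, end)."""

    start: int
    end: int
    cls: str
    n_samples: int
    start_s: float = math.nan
    end_s: float = math.nan


def margin_filter_mask(true_labels, change_margin: int = DEFAULT_CHANGE_MARGIN) -> np.ndarray:
    """Boolean mask excluding annotated change points and their neighbourhoods.

    A change point is the first sample of a new activity run.  For each one,
    the sample itself plus ``change_margin`` samples before and after are
    masked out (25 consecutive samples at the default margin), truncated at
    the series boundaries.
    """
    labels = np.asarray(true_labels, dtype=int)
    mask = np.ones(labels.size, dtype=bool)
    cps = np.flatnonzero(np.diff(labels)) + 1
    for i in cps:
        mask[max(i - change_margin, 0) : i + change_margin + 1] = False
    return mask


def confusion(true_labels, pred_labels, mask: Optional[np.ndarray] = None) -> ConfusionCounts:
    """Time-point confusion counts over masked-in points (walking = positive)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label series must have equal length")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != t.shape:
            raise ValueError("mask length mismatch")
        t, p = t[mask], p[mask]
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when nothing was predicted walking."""
    return _ratio(c.tp, c.tp + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total; NaN on empty counts."""
    return _ratio(c.tp + c.tn, c.total)


def detection_prevalence(c: ConfusionCounts) -> float:
    """(TP + FP) / total: the fraction of points *predicted* walking."""
    return _ratio(c.tp + c.fp, c.total)


def prevalence(c: ConfusionCounts) -> float:
    """(TP + FN) / total: the fraction of points *actually* walking."""
    return _ratio(c.tp + c.fn, c.total)


_PAIR_CLS = {(1, 1): "TP", (0, 1): "FP", (1, 0): "FN", (0, 0): "TN"}


def _run_segments(
    classes: Sequence[str],
    positions: np.ndarray,
    times: Optional[np.ndarray],
) -> list[Segment]:
    """Maximal runs of constant class over (possibly gapped) positions."""
    segments: list[Segment] = []
    if len(classes) == 0:
        return segments
    dt = float(times[1] - times[0]) if times is not None and times.size >= 2 else 0.0
    run_start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[i - 1]:
            first, last = int(positions[run_start]), int(positions[i - 1])
            seg = Segment(
                start=first,
                end=last + 1,
                cls=classes[i - 1],
                n_samples=i - run_start,
            )
            if times is not None:
                seg.start_s = float(times[first])
                seg.end_s = float(times[last] + dt)
            segments.append(seg)
            run_start = i
    return segments


def combined_segmentation(
    true_labels,
    pred_labels,
    mask: Optional[np.ndarray] = None,
    times: Optional[np.ndarray] = None,
) -> list[Segment]:
    """Four-class segmentation of the (true, predicted) label pairs.

    Each point is coded TP (1,1), FP (0,1), FN (1,0) or TN (0,0); maximal
    runs of constant code become segments.  When a margin `mask` is given,
    masked-out points are removed before run-length encoding, so runs
    separated only by a masked gap merge iff their classes match.
    ``n_samples`` counts the masked-in points of each segment; ``start``/
    ``end`` are positions in the original series.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label series must have equal length")
    positions = np.arange(t.size)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        t, p, positions = t[mask], p[mask], positions[mask]
    if times is not None:
        times = np.asarray(times, dtype=float)
    classes = [_PAIR_CLS[(int(a), int(b))] for a, b in zip(t, p)]
    return _run_segments(classes, positions, times)


def segments_from_labels(labels, times: Optional[np.ndarray] = None) -> list[Segment]:
    """Two-class (walking / non-walking) segmentation of one label series."""
    lab = np.asarray(labels, dtype=int)
    classes = ["walking" if v else "non-walking" for v in lab]
    if times is not None:
        times = np.asarray(times, dtype=float)
    return _run_segments(classes, np.arange(lab.size), times)


def segment_confusion(
    segments: Sequence[Segment], *, weight_by_length: bool = False
) -> ConfusionCounts:
    """Confusion counts over a four-class segmentation.

    By default each segment counts once regardless of duration; with
    ``weight_by_length=True`` each segment contributes its sample count
    instead (a non-default variant, since session-level scoring is the point).
    """
    if not segments:
        raise ValueError("empty segmentation")
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for seg in segments:
        if seg.cls not in counts:
            raise ValueError(f"not a four-class segmentation (class {seg.cls!r})")
        counts[seg.cls] += seg.n_samples if weight_by_length else 1
    return ConfusionCounts(tp=counts["TP"], fp=counts["FP"], fn=counts["FN"], tn=counts["TN"])


def metrics_report(
    true_labels,
    pred_labels,
    change_margin: int = DEFAULT_CHANGE_MARGIN,
    times: Optional[np.ndarray] = None,
) -> dict:
    """Bundle time-point and segment metrics for one prediction series."""
    mask = margin_filter_mask(true_labels, change_margin)
    c = confusion(true_labels, pred_labels, mask)
    segs = combined_segmentation(true_labels, pred_labels, mask, times)
    if segs:
        sc = segment_confusion(segs)
    else:  # every point masked out
        sc = ConfusionCounts(0, 0, 0, 0)
    return {
        "counts": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
        "precision": precision(c),
        "accuracy": accuracy(c),
        "detection_prevalence": detection_prevalence(c),
        "prevalence": prevalence(c),
        "segment_counts": {"tp": sc.tp, "fp": sc.fp, "fn": sc.fn, "tn": sc.tn},
        "segment_precision": precision(sc),
        "segment_accuracy": accuracy(sc),
        "n_masked_in": int(mask.sum()),
        "change_margin": change_margin,
    }
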