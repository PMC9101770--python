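"""Feature transforms: from unit-quaternion time series to the 2-D feature space.

The transform chain turns a hip-orientation recording into the two predictors
used by every classifier downstream:

1. finite differencing (``qfdts``): the incremental rotation q_ℓ⁻¹ q_{ℓ+1}
   between consecutive samples;
2. geodesic distances (``qdts``): the rotation angle, in radians, of each
   increment — a real-valued series of length P−1;
3. a left-hand sliding-window *circular mean* of those angles
   (``local_circular_mean``) and a sliding-window *circular standard
   deviation* of the smoothed series (``local_circular_sd``).

Windows are left-hand (the h past samples plus the current one) so every
value depends only on the past: the same features can be computed on-the-fly
on a sensor chip with O(h) memory, which :class:`StreamingFeatureExtractor`
demonstrates by reproducing the batch output bit for bit.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import quaternions as quat

__all__ = [
    "UQTSTrial",
    "RealSeries",
    "FeatureTable",
    "NormalizationStats",
    "qfdts",
    "qdts",
    "local_circular_mean",
    "local_circular_sd",
    "build_features",
    "normalize_features",
    "StreamingFeatureExtractor",
]

#: Default sliding-window size in samples: 0.5 s at 100 Hz.
DEFAULT_WINDOW = 50

_TIME_TOL = 1e-6


@dataclass
class UQTSTrial:
    """A timestamped unit-quaternion time series with optional activity labels.

    Parameters
    ----------
    times
        Seconds, on a uniform grid (step constant within 1e-6 s).
    quaternions
        Array of shape (P, 4) in (w, x, y, z) order; unit-norm within 1e-6.
    labels
        Optional per-sample binary marks, 1 = walking.
    """

    times: np.ndarray
    quaternions: np.ndarray
    labels: Optional[np.ndarray] = None
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.quaternions = quat.as_quat_array(self.quaternions)
        if self.times.ndim != 1 or self.quaternions.shape != (self.times.size, 4):
            raise ValueError("times must be 1-D and quaternions of shape (P, 4)")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(steps) - np.min(steps) > _TIME_TOL:
                raise ValueError("times must lie on a uniform grid (within 1e-6 s)")
        quat.validate_unit(self.quaternions, name="trial quaternion")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.times.shape:
                raise ValueError("labels must have the same length as times")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary (0/1)")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples for a time step")
        return float(self.times[1] - self.times[0])


@dataclass
class RealSeries:
    """A timestamped real-valued series (no missing values)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if not np.isfinite(self.values).all():
            raise ValueError("series values must be finite")


@dataclass
class FeatureTable:
    """Per-time-point feature pairs (lm, lsd): the classifiers' whole input space."""

    times: np.ndarray
    lm: np.ndarray
    lsd: np.ndarray
    label: Optional[np.ndarray] = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lm = np.asarray(self.lm, dtype=float)
        self.lsd = np.asarray(self.lsd, dtype=float)
        n = self.times.size
        if self.lm.shape != (n,) or self.lsd.shape != (n,):
            raise ValueError("all feature columns must share one length")
        if not (np.isfinite(self.lm).all() and np.isfinite(self.lsd).all()):
            raise ValueError("features must be finite")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)
            if self.label.shape != (n,):
                raise ValueError("label column length mismatch")

    def __len__(self) -> int:
        return self.times.size

    @property
    def X(self) -> np.ndarray:
        """Feature matrix of shape (n, 2), columns (lm, lsd)."""
        return np.column_stack([self.lm, self.lsd])


@dataclass(frozen=True)
class NormalizationStats:
    """Centering/scaling constants for the two feature columns (scales > 0)."""

    lm_center: float
    lm_scale: float
    lsd_center: float
    lsd_scale: float

    def __post_init__(self) -> None:
        if not (self.lm_scale > 0 and self.lsd_scale > 0):
            raise ValueError("normalization scales must be strictly positive")


def qfdts(trial: UQTSTrial) -> UQTSTrial:
    """Quaternion finite difference series: element ℓ is q_ℓ⁻¹ q_{ℓ+1}.

    The result has length P−1; each element is the incremental rotation between
    consecutive samples and carries the timestamp of the *later* member of the
    pair (causality for online use).  Labels, when present, are realigned the
    same way.
    """
    if trial.n_samples < 2:
        raise ValueError("finite differencing needs at least two samples")
    q = trial.quaternions
    dq = quat.hamilton_product(quat.inverse(q[:-1]), q[1:])
    labels = None if trial.labels is None else trial.labels[1:]
    return UQTSTrial(
        times=trial.times[1:],
        quaternions=dq,
        labels=labels,
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
    )


def qdts(trial: UQTSTrial, *, fold_double_cover: bool = False) -> RealSeries:
    """Geodesic-distance series between consecutive quaternions, in radians.

    Element ℓ is the rotation angle between q_ℓ and q_{ℓ+1}; length P−1,
    values in [0, 2π] (or [0, π] with the double cover folded).
    """
    if trial.n_samples < 2:
        raise ValueError("distance series needs at least two samples")
    q = trial.quaternions
    d = quat.geodesic_distance(q[:-1], q[1:], fold_double_cover=fold_double_cover)
    return RealSeries(times=trial.times[1:], values=d)


def _circ_mean_window(w: np.ndarray) -> float:
    # direction of the window's mean resultant vector
    return math.atan2(float(np.sin(w).sum()), float(np.cos(w).sum()))


def _circ_sd_window(w: np.ndarray) -> float:
    # circular SD sqrt(-2 ln R̄); angles are re-centred on the window's first
    # element, which leaves the resultant length R̄ unchanged but yields exact
    # zeros for constant windows.
    if w.size == 1:
        return 0.0
    c = w - w[0]
    r = math.hypot(float(np.cos(c).sum()), float(np.sin(c).sum())) / w.size
    if r < 1e-15:  # antipodal window: resultant vanishes up to rounding
        return math.inf
    return math.sqrt(max(-2.0 * math.log(min(r, 1.0)), 0.0))


def local_circular_mean(d: RealSeries, h: int) -> RealSeries:
    """Left-hand sliding-window circular mean of an angle series.

    Element ℓ is atan2(Σ sin d_m, Σ cos d_m) with m over the window
    max(ℓ−h, 0)..ℓ (h past samples plus the current one; truncated, not
    padded, at the series start).  With h = 0 the input is returned verbatim.

    atan2 output lies in (−π, π]; distance series are non-negative and tightly
    clustered near 0 in practice, so no re-wrapping is applied.
    """
    h = _check_window(h)
    if h == 0:
        return RealSeries(times=d.times.copy(), values=d.values.copy())
    v = d.values
    out = np.empty_like(v)
    for ell in range(v.size):
        out[ell] = _circ_mean_window(v[max(ell - h, 0) : ell + 1])
    return RealSeries(times=d.times.copy(), values=out)


def local_circular_sd(dh: RealSeries, h: int, *, cap: Optional[float] = None) -> RealSeries:
    """Left-hand sliding-window circular standard deviation sqrt(−2 ln R̄).

    R̄ is the mean resultant length of the window's angles; the divisor is the
    actual (possibly truncated) window length.  Values are non-negative; a
    window with R̄ = 0 (perfectly antipodal angles) has infinite circular SD
    and is replaced by `cap` (default: the maximum finite value in the series)
    with a warning.  With h = 0 every window holds one angle and the result is
    all zeros.
    """
    h = _check_window(h)
    v = dh.values
    out = np.empty_like(v)
    if h == 0:
        out.fill(0.0)
        return RealSeries(times=dh.times.copy(), values=out)
    for ell in range(v.size):
        out[ell] = _circ_sd_window(v[max(ell - h, 0) : ell + 1])
    infinite = ~np.isfinite(out)
    if infinite.any():
        fill = cap if cap is not None else float(np.max(out[~infinite], initial=0.0))
        warnings.warn(
            f"{int(infinite.sum())} window(s) had zero resultant length; "
            f"capping infinite circular SD at {fill:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        out[infinite] = fill
    return RealSeries(times=dh.times.copy(), values=out)


def _check_window(h: int) -> int:
    if not isinstance(h, (int, np.integer)) or h < 0:
        raise ValueError(f"window size must be a non-negative integer, got {h!r}")
    return int(h)


def build_features(
    trial: UQTSTrial,
    h: int = DEFAULT_WINDOW,
    *,
    fold_double_cover: bool = False,
) -> FeatureTable:
    """Chain qdts → local circular mean → local circular SD into a feature table.

    Labels attach by timestamp; the first raw sample, consumed by the finite
    difference, is dropped.
    """
    d = qdts(trial, fold_double_cover=fold_double_cover)
    lm = local_circular_mean(d, h)
    lsd = local_circular_sd(lm, h)
    labels = None if trial.labels is None else trial.labels[1:]
    return FeatureTable(
        times=d.times,
        lm=lm.values,
        lsd=lsd.values,
        label=labels,
        trial_id=trial.trial_id,
    )


def normalize_features(
    table: FeatureTable, stats: Optional[NormalizationStats] = None
) -> tuple[FeatureTable, NormalizationStats]:
    """Z-score the two feature columns.

    When `stats` is given (training-derived), it is applied without
    re-estimation; otherwise centers/scales are estimated from `table`
    (population SD, ddof=0) and returned for reuse at prediction time.

    Raises
    ------
    ValueError
        If a feature column is constant (zero scale).
    """
    if stats is None:
        lm_scale = float(np.std(table.lm))
        lsd_scale = float(np.std(table.lsd))
        if lm_scale == 0.0 or lsd_scale == 0.0:
            raise ValueError("cannot normalize a constant feature column")
        stats = NormalizationStats(
            lm_center=float(np.mean(table.lm)),
            lm_scale=lm_scale,
            lsd_center=float(np.mean(table.lsd)),
            lsd_scale=lsd_scale,
        )
    out = replace(
        table,
        lm=(table.lm - stats.lm_center) / stats.lm_scale,
        lsd=(table.lsd - stats.lsd_center) / stats.lsd_scale,
    )
    return out, stats


class StreamingFeatureExtractor:
    """Online feature computation with O(h) memory.

    Feeding a trial sample-by-sample through :meth:`push` reproduces
    :func:`build_features` element-wise exactly: both paths evaluate the same
    window kernels on the same window contents.

    The first sample yields no output (the finite difference needs two
    points); early windows are truncated to the available history.
    """

    def __init__(self, h: int = DEFAULT_WINDOW, *, fold_double_cover: bool = False):
        self.h = _check_window(h)
        self.fold_double_cover = fold_double_cover
        self._prev_q: Optional[np.ndarray] = None
        self._prev_t: Optional[float] = None
        self._d_window: deque = deque(maxlen=self.h + 1)
        self._lm_window: deque = deque(maxlen=self.h + 1)

    def push(self, q, t: float) -> Optional[tuple[float, float]]:
        """Consume one sample; return (lm, lsd) for its time point, or None."""
        q = quat.validate_unit(q, name="streamed quaternion")
        if self._prev_t is not None and t <= self._prev_t:
            raise ValueError(f"out-of-order timestamp: {t} after {self._prev_t}")
        if self._prev_q is None:
            self._prev_q, self._prev_t = q, t
            return None
        d = float(
            quat.geodesic_distance(self._prev_q, q, fold_double_cover=self.fold_double_cover)
        )
        self._prev_q, self._prev_t = q, t
        self._d_window.append(d)
        if self.h == 0:
            lm = d
        else:
            lm = _circ_mean_window(np.array(self._d_window))
        self._lm_window.append(lm)
        if self.h == 0:
            lsd = 0.0
        else:
            lsd = _circ_sd_window(np.array(self._lm_window))
            if not math.isfinite(lsd):
                lsd = 0.0  # degenerate antipodal window; no trial-wide cap online
        return lm, lsd
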