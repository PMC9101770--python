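"""Training, tuning and a posteriori smoothing of walking recognition models.

A walking activity recognition model (WARM) is the triple

    feature transform (window h)  →  tuned classifier  →  change-point smoothing.

Classifiers see only the 2-D normalized feature space (lm, lsd) and predict
each time point independently; smoothing then restores temporal coherence by
merging change points closer than τ seconds and relabelling the resulting
intervals by their walking fraction against a threshold η.

Hyper-parameters are tuned under trial-grouped cross-validation (no time
point of a trial ever appears on both sides of a fold) with a
prevalence-matched one-standard-error strategy applied in six fixed steps:

1. find the grid point whose mean detection prevalence is closest to the
   actual walking prevalence of the training data;
2. keep grid points within one standard error of that optimum;
3. among survivors, find the highest mean precision;
4. keep those within one standard error of it;
5. the same filter for accuracy;
6. break remaining ties by model simplicity (per classifier family; for
   smoothing: highest η, then smallest τ).

Detection-prevalence matching is what keeps the model honest: a classifier
that predicts walking far more (or less) often than walking actually occurs
is useless for downstream gait analysis no matter its precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import metrics as mx
from .features import (
    DEFAULT_WINDOW,
    FeatureTable,
    NormalizationStats,
    UQTSTrial,
    build_features,
    normalize_features,
)

__all__ = [
    "SplitPlan",
    "ClassifierSpec",
    "TuningRecord",
    "SmoothingParams",
    "WARMModel",
    "default_grid",
    "default_smoothing_grids",
    "split_trials",
    "make_cv_folds",
    "fit_classifier",
    "tune_classifier",
    "predict_raw",
    "smooth_predictions",
    "tune_smoothing",
    "select_six_steps",
    "records_to_frame",
]

FAMILIES = ("decision_tree", "rbf_svm", "knn", "logistic")


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitPlan:
    """Trial-level split: held-out fraction plus grouped CV folds."""

    test_fraction: float = 0.25
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


def split_trials(trials: Sequence, plan: SplitPlan) -> tuple[list, list]:
    """Partition trials (never time points) into train and test sets."""
    n = len(trials)
    if n < 4:
        raise ValueError("need at least 4 trials to split")
    n_test = max(1, round(n * plan.test_fraction))
    order = np.random.default_rng(plan.seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [trials[i] for i in range(n) if i not in test_idx]
    test = [trials[i] for i in range(n) if i in test_idx]
    return train, test


def make_cv_folds(train_trials: Sequence, plan: SplitPlan) -> list[tuple[list, list]]:
    """Grouped k-fold: each trial lands in exactly one assessment fold.

    Folds are sized as evenly as possible (e.g. 21 trials → assessment sizes
    5, 4, 4, 4, 4).
    """
    n = len(train_trials)
    k = plan.cv_folds
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} trials")
    order = np.random.default_rng(plan.seed + 1).permutation(n)
    fold_of = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        fold_of[idx] = rank % k
    folds = []
    for f in range(k):
        analysis = [train_trials[i] for i in range(n) if fold_of[i] != f]
        assessment = [train_trials[i] for i in range(n) if fold_of[i] == f]
        folds.append((analysis, assessment))
    return folds


# ---------------------------------------------------------------------------
# classifiers


def default_grid(family: str) -> dict[str, list]:
    """Default per-family tuning grids."""
    if family == "decision_tree":
        return {
            "cost_complexity": [10.0**e for e in range(-10, 0)],
            "tree_depth": list(range(1, 11)),
        }
    if family == "rbf_svm":
        return {
            "cost": [2.0**e for e in range(-5, 6)],
            "rbf_sigma": [10.0**e for e in range(-10, 1)],
        }
    if family == "knn":
        return {"neighbors": list(range(1, 68, 2)), "dist_power": [1, 2]}
    if family == "logistic":
        return {"threshold": [round(0.05 * i, 2) for i in range(1, 20)]}
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class ClassifierSpec:
    """A classifier family plus its hyper-parameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if not self.grid:
            self.grid = default_grid(self.family)

    def combinations(self) -> list[dict]:
        names = list(self.grid)
        return [
            dict(zip(names, values))
            for values in itertools.product(*(self.grid[n] for n in names))
        ]


def _triangular_weights(dist: np.ndarray) -> np.ndarray:
    """Triangular kernel over neighbour distances: weight 1 at distance 0,
    decaying linearly to (almost) 0 at the farthest neighbour."""
    dmax = dist.max(axis=-1, keepdims=True)
    safe = np.where(dmax > 0, dmax, 1.0)
    w = 1.0 - dist / (safe * (1.0 + 1e-9))
    return np.where(dmax > 0, w, 1.0)


@dataclass
class FittedClassifier:
    """A fitted per-time-point classifier (family + params + estimator)."""

    family: str
    params: dict
    estimator: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.family == "logistic":
            proba = self.estimator.predict_proba(X)[:, 1]
            return (proba >= self.params["threshold"]).astype(int)
        return np.asarray(self.estimator.predict(X), dtype=int)


def fit_classifier(spec_or_family, params: dict, X: np.ndarray, y: np.ndarray) -> FittedClassifier:
    """Fit one classifier at one grid point on normalized features.

    Families: CART decision tree with cost-complexity pruning, soft-margin SVM
    with Gaussian kernel exp(−sigma‖u−v‖²), k-NN with Minkowski power p and
    triangular distance weights, and unpenalized logistic regression whose
    probability is thresholded into a hard label.
    """
    family = spec_or_family.family if isinstance(spec_or_family, ClassifierSpec) else spec_or_family
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if family == "decision_tree":
        est = DecisionTreeClassifier(
            ccp_alpha=params["cost_complexity"],
            max_depth=params["tree_depth"],
            random_state=0,
        )
    elif family == "rbf_svm":
        est = SVC(C=params["cost"], kernel="rbf", gamma=params["rbf_sigma"])
    elif family == "knn":
        est = KNeighborsClassifier(
            n_neighbors=params["neighbors"],
            p=params["dist_power"],
            weights=_triangular_weights,
        )
    elif family == "logistic":
        # unpenalized logit: the 2-D feature space needs no regularization
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    est.fit(X, y)
    return FittedClassifier(family=family, params=dict(params), estimator=est)


# ---------------------------------------------------------------------------
# tuning records and the six-step selection


@dataclass
class TuningRecord:
    """Per-fold and aggregated metrics for one hyper-parameter combination."""

    params: dict
    fold_detection_prevalence: np.ndarray
    fold_precision: np.ndarray
    fold_accuracy: np.ndarray

    def _agg(self, values: np.ndarray) -> tuple[float, float]:
        mean = float(np.mean(values))
        k = values.size
        se = float(np.std(values, ddof=1) / math.sqrt(k)) if k > 1 else 0.0
        return mean, se

    @property
    def mean_dp(self) -> float:
        return self._agg(self.fold_detection_prevalence)[0]

    @property
    def se_dp(self) -> float:
        return self._agg(self.fold_detection_prevalence)[1]

    @property
    def mean_precision(self) -> float:
        return self._agg(self.fold_precision)[0]

    @property
    def se_precision(self) -> float:
        return self._agg(self.fold_precision)[1]

    @property
    def mean_accuracy(self) -> float:
        return self._agg(self.fold_accuracy)[0]

    @property
    def se_accuracy(self) -> float:
        return self._agg(self.fold_accuracy)[1]


def records_to_frame(records: Sequence[TuningRecord]) -> pd.DataFrame:
    """Audit table: one row per grid point with per-fold and aggregate metrics."""
    rows = []
    for r in records:
        row = dict(r.params)
        for i, (dp, pr, ac) in enumerate(
            zip(r.fold_detection_prevalence, r.fold_precision, r.fold_accuracy)
        ):
            row[f"fold{i}_detection_prevalence"] = dp
            row[f"fold{i}_precision"] = pr
            row[f"fold{i}_accuracy"] = ac
        row.update(
            mean_detection_prevalence=r.mean_dp,
            se_detection_prevalence=r.se_dp,
            mean_precision=r.mean_precision,
            se_precision=r.se_precision,
            mean_accuracy=r.mean_accuracy,
            se_accuracy=r.se_accuracy,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def simplicity_key(family: str) -> Callable[[dict], tuple]:
    """Tie-break ordering per family (smaller tuple = simpler model)."""
    if family == "decision_tree":
        return lambda p: (p["cost_complexity"], p["tree_depth"])
    if family == "rbf_svm":
        return lambda p: (p["cost"],)
    if family == "knn":
        return lambda p: (p["neighbors"],)
    if family == "logistic":
        return lambda p: (-p["threshold"],)
    if family == "smoothing":
        return lambda p: (-p["eta"], p["tau"])
    raise ValueError(f"no simplicity rule for {family!r}")


def select_six_steps(
    records: Sequence[TuningRecord],
    actual_prevalence: float,
    key: Callable[[dict], tuple],
) -> TuningRecord:
    """Apply the six-step prevalence-matched one-standard-error selection.

    "Within one standard error" is measured with the SE of the step's optimal
    record.  Records with undefined (NaN) means are skipped by the step that
    needs them; metric filters that would empty the survivor set (all NaN)
    leave it unchanged.
    """
    if not records:
        raise ValueError("no tuning records to select from")

    # 1-2: detection prevalence closest to the actual prevalence, one-SE band
    valid = [r for r in records if math.isfinite(r.mean_dp)]
    if not valid:
        raise ValueError("detection prevalence undefined for every grid point")
    opt = min(valid, key=lambda r: abs(r.mean_dp - actual_prevalence))
    survivors = [r for r in valid if abs(r.mean_dp - opt.mean_dp) <= opt.se_dp]
    if not survivors:  # pragma: no cover - opt always survives its own band
        raise RuntimeError("one-SE prevalence band retained nothing")

    # 3-4: highest precision, one-SE band
    survivors = _one_se_max(survivors, lambda r: (r.mean_precision, r.se_precision))
    # 5: highest accuracy, one-SE band
    survivors = _one_se_max(survivors, lambda r: (r.mean_accuracy, r.se_accuracy))
    # 6: simplicity
    return min(survivors, key=lambda r: key(r.params))


def _one_se_max(records: list[TuningRecord], stat) -> list[TuningRecord]:
    defined = [r for r in records if math.isfinite(stat(r)[0])]
    if not defined:
        return records
    best = max(defined, key=lambda r: stat(r)[0])
    best_mean, best_se = stat(best)
    return [r for r in defined if stat(r)[0] >= best_mean - best_se]


# ---------------------------------------------------------------------------
# cross-validated metric evaluation


def _pooled_metrics(conf: mx.ConfusionCounts) -> tuple[float, float, float]:
    return (
        mx.detection_prevalence(conf),
        mx.precision(conf),
        mx.accuracy(conf),
    )


def _pool_counts(counts: Sequence[mx.ConfusionCounts]) -> mx.ConfusionCounts:
    return mx.ConfusionCounts(
        tp=sum(c.tp for c in counts),
        fp=sum(c.fp for c in counts),
        fn=sum(c.fn for c in counts),
        tn=sum(c.tn for c in counts),
    )


def actual_walking_prevalence(
    tables: Sequence[FeatureTable], change_margin: int = mx.DEFAULT_CHANGE_MARGIN
) -> float:
    """Walking fraction over pooled time points after margin filtering."""
    walking = 0
    total = 0
    for tab in tables:
        mask = mx.margin_filter_mask(tab.label, change_margin)
        walking += int(tab.label[mask].sum())
        total += int(mask.sum())
    return walking / total


def _fit_fold_normalization(tables: Sequence[FeatureTable]):
    lm = np.concatenate([t.lm for t in tables])
    lsd = np.concatenate([t.lsd for t in tables])
    lm_scale, lsd_scale = float(np.std(lm)), float(np.std(lsd))
    if lm_scale == 0.0 or lsd_scale == 0.0:
        raise ValueError("cannot normalize a constant feature column")
    return NormalizationStats(
        lm_center=float(np.mean(lm)),
        lm_scale=lm_scale,
        lsd_center=float(np.mean(lsd)),
        lsd_scale=lsd_scale,
    )


def _stack_xy(tables: Sequence[FeatureTable], stats: NormalizationStats):
    X = np.concatenate([normalize_features(t, stats)[0].X for t in tables])
    y = np.concatenate([t.label for t in tables])
    return X, y


def tune_classifier(
    spec: ClassifierSpec,
    folds: Sequence[tuple[Sequence[FeatureTable], Sequence[FeatureTable]]],
    change_margin: int = mx.DEFAULT_CHANGE_MARGIN,
) -> tuple[dict, list[TuningRecord]]:
    """Grid-tune one classifier family under trial-grouped CV.

    `folds` holds (analysis, assessment) lists of labelled feature tables.
    Returns the selected hyper-parameters and the full audit record list.
    """
    combos = spec.combinations()
    all_analysis = {id(t): t for analysis, _ in folds for t in analysis}
    prev_ref = actual_walking_prevalence(list(all_analysis.values()), change_margin)

    fold_dp = np.empty((len(combos), len(folds)))
    fold_pr = np.empty_like(fold_dp)
    fold_ac = np.empty_like(fold_dp)

    for f, (analysis, assessment) in enumerate(folds):
        stats = _fit_fold_normalization(analysis)
        X_an, y_an = _stack_xy(analysis, stats)
        assess_X = [normalize_features(t, stats)[0].X for t in assessment]
        assess_y = [t.label for t in assessment]
        assess_mask = [mx.margin_filter_mask(y, change_margin) for y in assess_y]
        for c, params in enumerate(combos):
            clf = fit_classifier(spec.family, params, X_an, y_an)
            counts = [
                mx.confusion(y, clf.predict(X), m)
                for X, y, m in zip(assess_X, assess_y, assess_mask)
            ]
            fold_dp[c, f], fold_pr[c, f], fold_ac[c, f] = _pooled_metrics(_pool_counts(counts))

    records = [
        TuningRecord(
            params=params,
            fold_detection_prevalence=fold_dp[c],
            fold_precision=fold_pr[c],
            fold_accuracy=fold_ac[c],
        )
        for c, params in enumerate(combos)
    ]
    best = select_six_steps(records, prev_ref, simplicity_key(spec.family))
    return dict(best.params), records


# ---------------------------------------------------------------------------
# a posteriori smoothing


@dataclass(frozen=True)
class SmoothingParams:
    """Change-point merge threshold τ (seconds) and walking-fraction gate η."""

    tau: float
    eta: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie in (0, 1)")


def default_smoothing_grids() -> tuple[np.ndarray, np.ndarray]:
    """τ ∈ 0:0.05:3 s (3 s = the pause length between scripted activities,
    beyond which change points are never 'too close'); η ∈ 0.05:0.05:0.95."""
    taus = np.round(np.arange(0.0, 3.0 + 1e-9, 0.05), 2)
    etas = np.round(np.arange(0.05, 0.95 + 1e-9, 0.05), 2)
    return taus, etas


def _merge_change_points(cps: np.ndarray, times: np.ndarray, tau: float) -> list[int]:
    # single left-to-right pass; distance always measured to the last RETAINED
    # change point; trial boundaries are not change points and never discard
    kept: list[int] = []
    for i in cps:
        if not kept or times[i] - times[kept[-1]] >= tau:
            kept.append(int(i))
    return kept


def smooth_predictions(raw, times, params: SmoothingParams) -> np.ndarray:
    """A posteriori smoothing of per-time-point predictions.

    (1) change points are indices where the raw label changes; (2) change
    points closer than τ seconds to the previously retained one are discarded
    in one left-to-right pass; (3) every interval between retained change
    points (including the leading and trailing runs) is relabelled walking iff
    its fraction of raw walking predictions exceeds η.
    """
    raw = np.asarray(raw, dtype=int)
    times = np.asarray(times, dtype=float)
    if raw.shape != times.shape:
        raise ValueError("raw predictions and times must have equal length")
    if raw.size == 0:
        return raw.copy()
    cps = np.flatnonzero(np.diff(raw)) + 1
    kept = _merge_change_points(cps, times, params.tau)
    bounds = np.concatenate([[0], kept, [raw.size]]).astype(int)
    out = np.empty_like(raw)
    for a, b in zip(bounds[:-1], bounds[1:]):
        frac = float(raw[a:b].mean())
        out[a:b] = 1 if frac > params.eta else 0
    return out


def tune_smoothing(
    fold_predictions: Sequence[Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]],
    actual_prev: float,
    tau_grid: Optional[np.ndarray] = None,
    eta_grid: Optional[np.ndarray] = None,
    change_margin: int = mx.DEFAULT_CHANGE_MARGIN,
) -> tuple[SmoothingParams, list[TuningRecord]]:
    """Tune (τ, η) on per-fold raw predictions with the six-step strategy.

    `fold_predictions[f]` is a list of (times, true_labels, raw_pred) triples,
    one per assessment trial of fold f, produced by the already-tuned
    classifier.  Simplicity order: highest η first, then smallest τ.
    """
    taus, etas = default_smoothing_grids()
    if tau_grid is not None:
        taus = np.asarray(tau_grid, dtype=float)
    if eta_grid is not None:
        etas = np.asarray(eta_grid, dtype=float)

    combos = [(float(t), float(e)) for t in taus for e in etas]
    index = {c: i for i, c in enumerate(combos)}
    n_folds = len(fold_predictions)
    agg = np.zeros((len(combos), n_folds, 4), dtype=np.int64)  # tp fp fn tn

    for f, trials in enumerate(fold_predictions):
        for times, y_true, raw in trials:
            mask = mx.margin_filter_mask(y_true, change_margin)
            cps = np.flatnonzero(np.diff(raw)) + 1
            for tau in taus:
                kept = _merge_change_points(cps, times, float(tau))
                bounds = np.concatenate([[0], kept, [raw.size]]).astype(int)
                sums = np.add.reduceat(raw, bounds[:-1])
                lens = np.diff(bounds)
                fracs = sums / lens
                for eta in etas:
                    interval_labels = (fracs > eta).astype(int)
                    smoothed = np.repeat(interval_labels, lens)
                    c = mx.confusion(y_true, smoothed, mask)
                    agg[index[(float(tau), float(eta))], f] += (c.tp, c.fp, c.fn, c.tn)

    records = []
    for (tau, eta), i in index.items():
        dp = np.empty(n_folds)
        pr = np.empty(n_folds)
        ac = np.empty(n_folds)
        for f in range(n_folds):
            conf = mx.ConfusionCounts(*agg[i, f].tolist())
            dp[f], pr[f], ac[f] = _pooled_metrics(conf)
        records.append(
            TuningRecord(
                params={"tau": tau, "eta": eta},
                fold_detection_prevalence=dp,
                fold_precision=pr,
                fold_accuracy=ac,
            )
        )
    best = select_six_steps(records, actual_prev, simplicity_key("smoothing"))
    return SmoothingParams(**best.params), records


# ---------------------------------------------------------------------------
# the assembled model


@dataclass
class WARMModel:
    """A self-contained walking recognizer: transform, classifier, smoothing."""

    classifier: FittedClassifier
    stats: NormalizationStats
    h: int = DEFAULT_WINDOW
    smoothing: Optional[SmoothingParams] = None
    fold_double_cover: bool = False

    def features(self, trial: UQTSTrial) -> FeatureTable:
        return build_features(trial, self.h, fold_double_cover=self.fold_double_cover)

    def predict(self, trial: UQTSTrial) -> tuple[np.ndarray, np.ndarray, FeatureTable]:
        """Return (raw, smoothed, feature_table) for one trial."""
        table = self.features(trial)
        raw = predict_raw_from_table(self, table)
        if self.smoothing is not None:
            smoothed = smooth_predictions(raw, table.times, self.smoothing)
        else:
            smoothed = raw.copy()
        return raw, smoothed, table


def predict_raw_from_table(model: WARMModel, table: FeatureTable) -> np.ndarray:
    normalized, _ = normalize_features(table, model.stats)
    return model.classifier.predict(normalized.X)


def predict_raw(model: WARMModel, trial: UQTSTrial) -> np.ndarray:
    """Per-time-point labels from the classifier alone (no temporal coupling)."""
    return predict_raw_from_table(model, model.features(trial))
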