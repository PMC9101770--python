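"""End-to-end experiment: simulate → transform → tune → smooth → evaluate.

Mirrors the study protocol: a dataset of ~90 s trials over a few subjects is
split 75/25 at the trial level; the training trials are tuned under grouped
5-fold cross-validation (classifier grid first, then the smoothing grid on
the tuned classifier's per-fold raw predictions); the final model is fitted
on the full training set and scored on the held-out trials with
margin-filtered time-point metrics and segment metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import metrics as mx
from .features import FeatureTable, UQTSTrial, build_features, normalize_features
from .pipeline import (
    ClassifierSpec,
    SmoothingParams,
    SplitPlan,
    TuningRecord,
    WARMModel,
    _fit_fold_normalization,
    _stack_xy,
    actual_walking_prevalence,
    fit_classifier,
    make_cv_folds,
    split_trials,
    tune_classifier,
    tune_smoothing,
)
from .simulate import TrialRecipe, simulate_dataset

__all__ = ["ExperimentResult", "TrainedWARM", "train_warm", "run_experiment", "evaluate_model"]


@dataclass
class TrainedWARM:
    """A tuned model plus the audit trail of its selection."""

    model: WARMModel
    classifier_params: dict
    smoothing_params: SmoothingParams
    classifier_records: list[TuningRecord]
    smoothing_records: list[TuningRecord]
    train_prevalence: float


@dataclass
class ExperimentResult:
    """Everything a run produces: the model, audits, and test-set metrics."""

    model: WARMModel
    classifier_params: dict
    smoothing_params: SmoothingParams
    classifier_records: list[TuningRecord]
    smoothing_records: list[TuningRecord]
    train_prevalence: float
    metrics_raw: dict
    metrics_smoothed: dict
    n_train_trials: int
    n_test_trials: int
    n_test_points: int


def train_warm(
    train_tables: Sequence[FeatureTable],
    plan: SplitPlan,
    family: str = "decision_tree",
    grid: Optional[dict] = None,
    tau_grid=None,
    eta_grid=None,
    h: int = 50,
    change_margin: int = mx.DEFAULT_CHANGE_MARGIN,
) -> TrainedWARM:
    """Tune and fit a WARM on per-trial labelled feature tables.

    Cross-validation folds partition *tables* (i.e. trials), never time
    points.  The classifier grid is tuned first; the smoothing grid is then
    tuned on the chosen classifier's per-fold raw predictions; the final
    classifier and normalization statistics are fitted on all tables pooled.
    """
    train_tables = list(train_tables)
    folds = make_cv_folds(train_tables, plan)
    spec = ClassifierSpec(family=family, grid=grid or {})
    best_params, clf_records = tune_classifier(spec, folds, change_margin)

    prev_ref = actual_walking_prevalence(train_tables, change_margin)
    fold_predictions = []
    for analysis, assessment in folds:
        stats = _fit_fold_normalization(analysis)
        X_an, y_an = _stack_xy(analysis, stats)
        clf = fit_classifier(family, best_params, X_an, y_an)
        triples = []
        for tab in assessment:
            X = normalize_features(tab, stats)[0].X
            triples.append((tab.times, tab.label, clf.predict(X)))
        fold_predictions.append(triples)
    smoothing, smo_records = tune_smoothing(
        fold_predictions, prev_ref, tau_grid, eta_grid, change_margin
    )

    final_stats = _fit_fold_normalization(train_tables)
    X_tr, y_tr = _stack_xy(train_tables, final_stats)
    final_clf = fit_classifier(family, best_params, X_tr, y_tr)
    model = WARMModel(classifier=final_clf, stats=final_stats, h=h, smoothing=smoothing)
    return TrainedWARM(
        model=model,
        classifier_params=best_params,
        smoothing_params=smoothing,
        classifier_records=clf_records,
        smoothing_records=smo_records,
        train_prevalence=prev_ref,
    )


def evaluate_model(
    model: WARMModel,
    trials: Sequence[UQTSTrial],
    change_margin: int = mx.DEFAULT_CHANGE_MARGIN,
) -> tuple[dict, dict]:
    """Pooled margin-filtered metrics (raw, smoothed) over a set of trials."""
    counts_raw = []
    counts_smo = []
    seg_raw = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    seg_smo = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for trial in trials:
        raw, smoothed, table = model.predict(trial)
        mask = mx.margin_filter_mask(table.label, change_margin)
        counts_raw.append(mx.confusion(table.label, raw, mask))
        counts_smo.append(mx.confusion(table.label, smoothed, mask))
        for seg in mx.combined_segmentation(table.label, raw, mask):
            seg_raw[seg.cls] += 1
        for seg in mx.combined_segmentation(table.label, smoothed, mask):
            seg_smo[seg.cls] += 1

    def bundle(counts, segs):
        pooled = mx.ConfusionCounts(
            tp=sum(c.tp for c in counts),
            fp=sum(c.fp for c in counts),
            fn=sum(c.fn for c in counts),
            tn=sum(c.tn for c in counts),
        )
        seg_counts = mx.ConfusionCounts(
            tp=segs["TP"], fp=segs["FP"], fn=segs["FN"], tn=segs["TN"]
        )
        return {
            "counts": pooled,
            "precision": mx.precision(pooled),
            "accuracy": mx.accuracy(pooled),
            "detection_prevalence": mx.detection_prevalence(pooled),
            "prevalence": mx.prevalence(pooled),
            "segment_counts": seg_counts,
            "segment_precision": mx.precision(seg_counts),
            "segment_accuracy": mx.accuracy(seg_counts),
            "n_points": pooled.total,
        }

    return bundle(counts_raw, seg_raw), bundle(counts_smo, seg_smo)


def run_experiment(
    seed: int = 0,
    n_trials: int = 28,
    n_subjects: int = 3,
    preset: str = "easy",
    family: str = "decision_tree",
    h: int = 50,
    grid: Optional[dict] = None,
    tau_grid=None,
    eta_grid=None,
    split_plan: Optional[SplitPlan] = None,
    trials: Optional[Sequence[UQTSTrial]] = None,
    change_margin: int = mx.DEFAULT_CHANGE_MARGIN,
) -> ExperimentResult:
    """Run the full pipeline on a synthetic dataset and score the held-out trials.

    Defaults reproduce the study conditions: 28 trials over 3 subjects at
    100 Hz / ~90 s each, window h = 50 (0.5 s), 75/25 trial split, grouped
    5-fold CV, decision-tree family with its full grid, smoothing grids
    τ ∈ 0:0.05:3 s and η ∈ 0.05:0.05:0.95.
    """
    if trials is None:
        recipe = TrialRecipe.preset(preset)
        trials = simulate_dataset(n_trials, n_subjects, recipe, seed=seed)
    plan = split_plan or SplitPlan(seed=seed)

    train_trials, test_trials = split_trials(list(trials), plan)
    train_tables = [build_features(t, h) for t in train_trials]
    trained = train_warm(
        train_tables,
        plan,
        family=family,
        grid=grid,
        tau_grid=tau_grid,
        eta_grid=eta_grid,
        h=h,
        change_margin=change_margin,
    )

    metrics_raw, metrics_smoothed = evaluate_model(trained.model, test_trials, change_margin)
    return ExperimentResult(
        model=trained.model,
        classifier_params=trained.classifier_params,
        smoothing_params=trained.smoothing_params,
        classifier_records=trained.classifier_records,
        smoothing_records=trained.smoothing_records,
        train_prevalence=trained.train_prevalence,
        metrics_raw=metrics_raw,
        metrics_smoothed=metrics_smoothed,
        n_train_trials=len(train_trials),
        n_test_trials=len(test_trials),
        n_test_points=metrics_smoothed["n_points"],
    )
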