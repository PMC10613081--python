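"""MI detection with classical classifiers under stratified 5-fold CV.

Four off-the-shelf classifiers (SVM, logistic regression, decision tree,
k-nearest-neighbour) are trained on 6-dimensional motion features — from a
single segmentation source, the averaging ensemble (AE) or the weighting
ensemble (WE) — with hyperparameters chosen by grid search on the training
portion of each fold.  Fusion weights for WE are calibrated per fold from
segment-wise IoU scores of the training clips only, so no information from
test clips leaks into either the weights or the hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ensemble import SegmentScore, WeightSet, accumulate_features, ensemble_weights
from .features import MotionFeature

CLASSIFIER_KINDS = ("svm", "lr", "dt", "knn")

#: Hyperparameter grids.  The C grids span 0.01..100 with four log-spaced
#: values; DT and KNN grids are the conventional small-sample choices.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.01, 0.1, 10.0, 100.0]},
    # l1_ratio 1.0 / 0.0 selects an L1 / L2 penalty under liblinear
    "lr": {"C": [0.01, 0.1, 10.0, 100.0], "l1_ratio": [1.0, 0.0]},
    "dt": {"max_depth": [5, 10, 25, None], "min_samples_split": [2, 5, 10]},
    "knn": {"n_neighbors": [2, 5, 10, 25, 50]},
}


class LeakageError(RuntimeError):
    """A test clip reached weight calibration or hyperparameter selection."""


@dataclass
class CVPlan:
    """Stratified fold assignment for every clip."""

    fold: np.ndarray      # (n,) fold index per clip, 0..n_folds-1
    n_folds: int
    seed: int

    def split(self):
        for f in range(self.n_folds):
            test = np.flatnonzero(self.fold == f)
            train = np.flatnonzero(self.fold != f)
            yield train, test


@dataclass
class EvalReport:
    """Confusion counts and threshold metrics for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    flags: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def make_cv_plan(labels, seed: int = 0, n_folds: int = 5) -> CVPlan:
    """Assign clips to stratified folds, deterministic in ``seed``."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need clips from both classes to stratify")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} clips; need >= {n_folds} "
            f"(reduce n_folds or enlarge the cohort)"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[test] = f
    return CVPlan(fold=fold, n_folds=n_folds, seed=seed)


def _make_estimator(kind: str, seed: int):
    """Estimator for ``kind``; scale-sensitive models get a standardizer."""
    if kind == "svm":
        base = SVC(random_state=seed)
    elif kind == "lr":
        base = LogisticRegression(solver="liblinear", max_iter=1000)
    elif kind == "dt":
        return DecisionTreeClassifier(random_state=seed)
    elif kind == "knn":
        base = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("clf", base)])


def grid_search_fit(
    X,
    y,
    kind: str,
    grid: dict | None = None,
    seed: int = 0,
    inner_folds: int = 3,
):
    """Fit ``kind`` with hyperparameters picked by inner stratified CV on F1.

    Returns ``(fitted_estimator, best_params)``.  KNN neighbour counts
    larger than the smallest inner training split are dropped up front.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    if np.unique(y).size < 2:
        raise ValueError("training labels must contain both classes")
    grid = dict(grid if grid is not None else DEFAULT_GRIDS[kind])
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    if kind == "knn":
        max_k = int(np.floor(len(y) * (inner_folds - 1) / inner_folds))
        grid["n_neighbors"] = [k for k in grid["n_neighbors"] if k <= max_k] or [
            max(1, max_k)
        ]
    est = _make_estimator(kind, seed)
    if isinstance(est, Pipeline):
        grid = {f"clf__{key}": val for key, val in grid.items()}
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="f1", cv=inner)
    search.fit(X, y)
    best = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return search.best_estimator_, best


def evaluate(preds, labels) -> EvalReport:
    """Confusion counts and the five threshold metrics (beta = 1).

    Metrics whose denominator is zero are reported as 0 and flagged.
    """
    p = np.asarray(preds).astype(int)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("preds and labels must have equal length")
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * prec * sens, prec + sens, "f1")
    acc = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    return EvalReport(tp, fp, tn, fn, sens, spec, prec, f1, acc, tuple(flags))


@dataclass
class CohortFeatures:
    """Per-clip motion features and segment scores for a whole cohort.

    ``mf[source]`` is the list of per-clip :class:`MotionFeature`;
    ``scores[source]`` the per-clip :class:`SegmentScore` against the
    reference segmentation (needed only for WE fusion).
    """

    clip_ids: list[str]
    labels: np.ndarray
    mf: dict[str, list[MotionFeature]]
    scores: dict[str, list[SegmentScore]] = field(default_factory=dict)

    @property
    def n_clips(self) -> int:
        return len(self.clip_ids)

    def feature_matrix(self, source: str) -> np.ndarray:
        return np.vstack([f.mf for f in self.mf[source]])


def calibrate_fold_weights(
    cohort: CohortFeatures,
    sources: list[str],
    calibration_idx: np.ndarray,
    forbidden_idx: np.ndarray | None = None,
) -> WeightSet:
    """Fusion weights from mean segment IoU over the calibration clips.

    ``forbidden_idx`` (the fold's test clips) must not intersect the
    calibration set — a violation raises :class:`LeakageError`.
    """
    if forbidden_idx is not None and np.intersect1d(calibration_idx, forbidden_idx).size:
        raise LeakageError("test clips present in weight calibration set")
    mean_scores = []
    for src in sources:
        M = np.vstack([cohort.scores[src][i].M for i in calibration_idx])
        mean_scores.append(
            SegmentScore(M=np.nanmean(M, axis=0), full_iou=float("nan"), source=src)
        )
    return ensemble_weights(mean_scores)


def fused_matrix(cohort: CohortFeatures, sources: list[str], weights: WeightSet) -> np.ndarray:
    """WE-fused feature matrix for every clip under fixed weights."""
    return np.vstack(
        [
            accumulate_features([cohort.mf[s][i] for s in sources], weights)
            for i in range(cohort.n_clips)
        ]
    )


def averaged_matrix(cohort: CohortFeatures, sources: list[str]) -> np.ndarray:
    from .ensemble import average_ensemble

    return np.vstack(
        [
            average_ensemble([cohort.mf[s][i] for s in sources])
            for i in range(cohort.n_clips)
        ]
    )


def run_experiment(
    cohort: CohortFeatures,
    sources: list[str],
    fusion_modes: tuple[str, ...] = ("single", "ae", "we"),
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS,
    seed: int = 0,
    n_folds: int = 5,
    grids: dict | None = None,
) -> pd.DataFrame:
    """Cross-validated MI-detection comparison across feature modes.

    Produces one row per (classifier, feature mode) with fold-mean and
    fold-s.d. of each metric plus pooled confusion counts.  Feature modes:
    ``single`` adds one row per source; ``ae``/``we`` fuse all ``sources``.
    WE weights are recalibrated inside each fold on training clips only.
    """
    plan = make_cv_plan(cohort.labels, seed=seed, n_folds=n_folds)
    y = cohort.labels

    mode_rows: list[tuple[str, str]] = []
    if "single" in fusion_modes:
        mode_rows += [("single", s) for s in sources]
    for m in ("ae", "we"):
        if m in fusion_modes:
            mode_rows.append((m, "+".join(sources)))

    records = []
    for clf in classifiers:
        for mode, tag in mode_rows:
            fold_reports: list[EvalReport] = []
            pooled_preds = np.empty(cohort.n_clips, dtype=int)
            for train, test in plan.split():
                if mode == "single":
                    X = cohort.feature_matrix(tag)
                elif mode == "ae":
                    X = averaged_matrix(cohort, sources)
                else:
                    w = calibrate_fold_weights(cohort, sources, train, forbidden_idx=test)
                    X = fused_matrix(cohort, sources, w)
                model, _ = grid_search_fit(
                    X[train], y[train], clf, grid=(grids or {}).get(clf), seed=seed
                )
                preds = model.predict(X[test])
                pooled_preds[test] = preds
                fold_reports.append(evaluate(preds, y[test]))
            pooled = evaluate(pooled_preds, y)
            rec = {"classifier": clf, "mode": mode, "features": tag}
            for metric in ("sensitivity", "specificity", "precision", "f1", "accuracy"):
                vals = np.array([getattr(r, metric) for r in fold_reports])
                rec[f"{metric}_mean"] = vals.mean()
                rec[f"{metric}_sd"] = vals.std(ddof=1)
                rec[f"{metric}_pooled"] = getattr(pooled, metric)
            rec.update(tp=pooled.tp, fp=pooled.fp, tn=pooled.tn, fn=pooled.fn)
            records.append(rec)
    return pd.DataFrame(records)
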