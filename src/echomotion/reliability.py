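"""Prediction-consistency analysis via Cohen's kappa.

A clinically useful detector should give the same answer regardless of
which segmentation source produced its features.  Consistency is measured
as Cohen's chance-corrected agreement between predictions of classifier
variants on a common test subset, in three scenarios: variants trained on
single-source features, variants trained on weighting-ensemble fusions of
different source pairs, and (for real data) human raters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import CohortFeatures, calibrate_fold_weights, fused_matrix, grid_search_fit
from sklearn.model_selection import train_test_split


@dataclass
class AgreementReport:
    """Pairwise kappa matrix over variants plus its mean for one scenario."""

    classifier: str
    scenario: str                 # 'single-feature' | 'ensemble-feature' | 'expert'
    variants: tuple[str, ...]
    kappa_matrix: np.ndarray      # symmetric, unit diagonal
    mean_kappa: float
    n_items: int


def cohen_kappa(preds_a, preds_b) -> float:
    """Cohen's kappa between two binary raters.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the raters' marginals.  When both raters are
    constant (p_e = 1) kappa is defined as 1 if they agree everywhere and
    0 otherwise, with a warning.
    """
    a = np.asarray(preds_a).astype(int)
    b = np.asarray(preds_b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need two equal-length non-empty 1-d prediction arrays")
    n = a.size
    p_o = float((a == b).mean())
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0 - 1e-15:
        warnings.warn("both raters constant; kappa degenerate")
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def pairwise_kappa(predictions: dict[str, np.ndarray]) -> tuple[np.ndarray, float]:
    """Symmetric kappa matrix over named raters and its off-diagonal mean."""
    names = list(predictions)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two raters")
    mat = np.eye(k)
    vals = []
    for i, j in combinations(range(k), 2):
        kij = cohen_kappa(predictions[names[i]], predictions[names[j]])
        mat[i, j] = mat[j, i] = kij
        vals.append(kij)
    return mat, float(np.mean(vals))


def rater_agreement(labels_by_rater: dict[str, np.ndarray]) -> AgreementReport:
    """Agreement among external raters (e.g. experts) on the same items."""
    mat, mean = pairwise_kappa(labels_by_rater)
    names = tuple(labels_by_rater)
    n = len(next(iter(labels_by_rater.values())))
    return AgreementReport("-", "expert", names, mat, mean, n)


def agreement_study(
    cohort: CohortFeatures,
    classifiers: tuple[str, ...],
    sources: list[str],
    n_items: int = 20,
    seed: int = 0,
    test_frac: float = 0.2,
) -> list[AgreementReport]:
    """Single-feature vs ensemble-feature consistency on a held-out subset.

    The cohort is split once (stratified) into a training portion and a
    held-out portion from which ``n_items`` clips are drawn.  For each
    classifier, scenario 'single-feature' trains one variant per source
    and scenario 'ensemble-feature' one variant per unordered source pair
    (features fused by WE with weights calibrated on the training clips);
    each report carries the pairwise kappa matrix over variant predictions
    on the common subset and its mean.
    """
    if len(sources) < 2:
        raise ValueError("need at least two sources to form variant sets")
    idx = np.arange(cohort.n_clips)
    train, held = train_test_split(
        idx, test_size=test_frac, stratify=cohort.labels, random_state=seed
    )
    rng = np.random.default_rng(seed)
    if held.size < n_items:
        warnings.warn(f"only {held.size} held-out clips; using all of them")
        items = held
    else:
        items = rng.choice(held, size=n_items, replace=False)
    y = cohort.labels

    reports: list[AgreementReport] = []
    for clf in classifiers:
        single: dict[str, np.ndarray] = {}
        for src in sources:
            X = cohort.feature_matrix(src)
            model, _ = grid_search_fit(X[train], y[train], clf, seed=seed)
            single[src] = model.predict(X[items])
        mat, mean = pairwise_kappa(single)
        reports.append(
            AgreementReport(clf, "single-feature", tuple(sources), mat, mean, items.size)
        )

        fused: dict[str, np.ndarray] = {}
        for pair in combinations(sources, 2):
            w = calibrate_fold_weights(cohort, list(pair), train, forbidden_idx=items)
            X = fused_matrix(cohort, list(pair), w)
            model, _ = grid_search_fit(X[train], y[train], clf, seed=seed)
            fused["+".join(pair)] = model.predict(X[items])
        mat, mean = pairwise_kappa(fused)
        reports.append(
            AgreementReport(
                clf, "ensemble-feature", tuple(fused), mat, mean, items.size
            )
        )
    return reports


def agreement_table(reports: list[AgreementReport]) -> pd.DataFrame:
    """Tidy (classifier, scenario, kappa) table of agreement results."""
    return pd.DataFrame(
        [
            {
                "classifier": r.classifier,
                "scenario": r.scenario,
                "kappa": r.mean_kappa,
                "n_items": r.n_items,
            }
            for r in reports
        ]
    )
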