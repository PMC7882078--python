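"""Classifier evaluation of miRNA biomarker panels.

Single markers and marker pairs are scored by stratified fivefold
cross-validated SVM classification (radial kernel with the e1071-style
defaults: cost 1, kernel width 1/n_features) plus ROC/AUC, with
sensitivity, specificity and accuracy computed from the pooled
out-of-fold confusion counts:

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TN + TP) / (TP + FP + TN + FN)

AUC uses the rank (Mann–Whitney) formulation with ties contributing ½,
which equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .descreen import CONTROL, DISEASE, ExpressionStudy

__all__ = [
    "ConfusionCounts",
    "PanelEval",
    "confusion_metrics",
    "roc_auc",
    "direct_auc",
    "cv_svm_eval",
    "panel_search",
    "evals_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PanelEval:
    panel: tuple[str, ...]
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    mean_single_auc: float | None = None


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    if counts.tp + counts.fn == 0 or counts.fp + counts.tn == 0:
        raise ValueError("a class is empty; metrics undefined")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.fp + counts.tn)
    acc = (counts.tn + counts.tp) / counts.total
    return sens, spec, acc


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via mid-ranks (ties count ½)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _labels_array(study: ExpressionStudy) -> np.ndarray:
    groups = study.sample_groups.loc[study.values.columns]
    return (groups == DISEASE).to_numpy(dtype=int)


def direct_auc(study: ExpressionStudy, mirna: str, orient: bool = True) -> float:
    """Dataset-level AUC using the raw expression of one miRNA as score.

    With ``orient`` (default) the score sign is chosen so the AUC is at
    least 0.5 on this data; the chosen orientation should then be frozen
    when scoring validation data.
    """
    scores = study.values.loc[mirna].to_numpy(dtype=float)
    labels = _labels_array(study)
    auc = roc_auc(scores, labels)
    return max(auc, 1 - auc) if orient else auc


def cv_svm_eval(
    study: ExpressionStudy,
    panel: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    svm_params: dict | None = None,
) -> PanelEval:
    """Stratified k-fold SVM evaluation of a marker panel.

    Per fold an RBF SVM (cost 1, gamma = 1/n_features) is fitted on the
    training folds; out-of-fold decision values are pooled for the AUC and
    out-of-fold hard predictions are pooled into the confusion counts for
    sensitivity/specificity/accuracy. Fully deterministic under a fixed
    seed.
    """
    missing = [m for m in panel if m not in study.values.index]
    if missing:
        raise KeyError(f"panel features not in matrix: {missing}")
    X = study.values.loc[list(panel)].to_numpy(dtype=float).T  # samples × features
    y = _labels_array(study)
    for j, name in enumerate(panel):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"feature {name!r} is constant", stacklevel=2)

    params = {"kernel": "rbf", "C": 1.0, "gamma": "auto"}  # gamma=1/n_features
    if svm_params:
        params.update(svm_params)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    decision = np.empty(len(y))
    pred = np.empty(len(y), dtype=int)
    for train, test in skf.split(X, y):
        clf = SVC(**params)
        clf.fit(X[train], y[train])
        decision[test] = clf.decision_function(X[test])
        pred[test] = clf.predict(X[test])
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    sens, spec, acc = confusion_metrics(counts)
    return PanelEval(
        panel=tuple(panel),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=roc_auc(decision, y),
    )


def panel_search(
    study: ExpressionStudy,
    candidates: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    mode: str = "svm",
) -> list[PanelEval]:
    """Evaluate all single markers and all unordered marker pairs.

    Each pair additionally carries the mean of its members' single-marker
    AUCs for comparison. ``mode="direct"`` scores single markers by their
    raw expression (orientation-corrected AUC) instead of the SVM. Output
    sorted by AUC descending.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates")
    singles: dict[str, PanelEval] = {}
    for m in candidates:
        if mode == "direct":
            auc = direct_auc(study, m)
            ev = cv_svm_eval(study, [m], folds=folds, seed=seed)
            singles[m] = PanelEval(
                panel=(m,),
                sensitivity=ev.sensitivity,
                specificity=ev.specificity,
                accuracy=ev.accuracy,
                auc=auc,
            )
        else:
            singles[m] = cv_svm_eval(study, [m], folds=folds, seed=seed)
    evals = list(singles.values())
    for a, b in combinations(candidates, 2):
        ev = cv_svm_eval(study, [a, b], folds=folds, seed=seed)
        evals.append(
            PanelEval(
                panel=ev.panel,
                sensitivity=ev.sensitivity,
                specificity=ev.specificity,
                accuracy=ev.accuracy,
                auc=ev.auc,
                mean_single_auc=(singles[a].auc + singles[b].auc) / 2,
            )
        )
    return sorted(evals, key=lambda e: (-e.auc, e.panel))


def evals_table(evals: Sequence[PanelEval]) -> pd.DataFrame:
    """Panel evaluations in the layout of a combined-biomarker table."""
    return pd.DataFrame(
        [
            {
                "panel": "/".join(e.panel),
                "sensitivity": e.sensitivity,
                "specificity": e.specificity,
                "accuracy": e.accuracy,
                "auc": e.auc,
                "mean_auc": e.mean_single_auc,
            }
            for e in evals
        ]
    )
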