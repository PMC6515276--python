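"""Class balancing, classifiers, cross-validation and experiment grids.

Six classifier families are provided: PCA+LDA, PCA+RBF-SVM, 1-nearest
neighbour, logistic regression, a 100-tree random forest and a one-hidden
-layer perceptron.  Evaluation is stratified k-fold cross-validation (10
folds by default) with class balancing to the mean class count —
minority classes oversampled with replacement, majority classes
undersampled.  The default protocol balances, standardises and fits PCA
inside the training folds only, which is leak-free; a ``global`` mode
that balances the whole dataset before folding is retained for protocol
comparisons.  Person-specific evaluation runs the same CV within each
subject and averages accuracies unweighted across subjects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fusion import LabeledDataset

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "EvalResult",
    "CLASSIFIER_KINDS",
    "build_estimator",
    "balance_classes",
    "run_cv",
    "person_specific_eval",
    "experiment_grid",
]

CLASSIFIER_KINDS = ("pca_lda", "pca_svm_rbf", "knn1", "logistic", "rf100", "mlp")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the six classifier configurations.

    The forest size (100) and the neighbour count (1) are fixed by
    protocol; hyperparameters the protocol leaves open (PCA variance
    retained, SVM C and gamma, MLP width and epochs) default to common
    toolkit conventions and are all overridable.
    """

    kind: str = "rf100"
    pca_variance_retained: float = 0.95
    svm_c: float = 1.0
    mlp_max_iter: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if not 0 < self.pca_variance_retained <= 1:
            raise ValueError("pca_variance_retained must be in (0, 1]")


def build_estimator(spec: ClassifierSpec, n_features: int, n_classes: int) -> Pipeline:
    """Instantiate the sklearn pipeline for a spec (standardisation first;
    PCA where the spec includes it)."""
    rs = spec.seed
    steps = [("scale", StandardScaler())]
    if spec.kind == "pca_lda":
        steps += [
            ("pca", PCA(spec.pca_variance_retained, svd_solver="full")),
            ("clf", LinearDiscriminantAnalysis()),
        ]
    elif spec.kind == "pca_svm_rbf":
        steps += [
            ("pca", PCA(spec.pca_variance_retained, svd_solver="full")),
            ("clf", SVC(C=spec.svm_c, kernel="rbf", gamma="auto", random_state=rs)),
        ]
    elif spec.kind == "knn1":
        steps += [("clf", KNeighborsClassifier(n_neighbors=1))]
    elif spec.kind == "logistic":
        steps += [("clf", LogisticRegression(max_iter=2000, random_state=rs))]
    elif spec.kind == "rf100":
        steps = [("clf", RandomForestClassifier(n_estimators=100, random_state=rs))]
    elif spec.kind == "mlp":
        hidden = math.ceil((n_features + n_classes) / 2)
        steps += [
            ("clf", MLPClassifier(
                hidden_layer_sizes=(hidden,), max_iter=spec.mlp_max_iter,
                random_state=rs,
            )),
        ]
    return Pipeline(steps)


@dataclass
class EvalResult:
    """Pooled cross-validation metrics, all on a 0-100 scale."""

    accuracy: float
    f_measure: float
    precision: float
    recall: float
    confusion: np.ndarray
    classes: np.ndarray
    config: dict
    seed: int
    per_subject: Optional[dict] = None


def _metrics(y_true, y_pred, config, seed) -> EvalResult:
    classes = np.unique(y_true)
    acc = 100.0 * float(np.mean(y_true == y_pred))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="weighted", zero_division=0
    )
    return EvalResult(
        accuracy=acc,
        f_measure=100.0 * float(f1),
        precision=100.0 * float(prec),
        recall=100.0 * float(rec),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        classes=classes,
        config=config,
        seed=seed,
    )


def _balance_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0) or classes.size == 0:
        raise ValueError("every class must be non-empty")
    target = int(round(float(np.mean(counts))))
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size > target:
            keep.append(rng.choice(idx, size=target, replace=False))
        elif idx.size < target:
            extra = rng.choice(idx, size=target - idx.size, replace=True)
            keep.append(np.concatenate([idx, extra]))
        else:
            keep.append(idx)
    return np.sort(np.concatenate(keep))


def balance_classes(ds: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Resample every class to the mean original class count: minorities
    oversampled with replacement (exact duplicate rows), majorities
    undersampled without replacement.  Deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    return ds.subset(_balance_indices(ds.y, rng))


def run_cv(
    ds: LabeledDataset,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    balanced: str = "within_fold",
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold cross-validation.

    ``within_fold`` (default, leak-free): each training fold is balanced
    and all fitting — scaler, PCA, classifier — happens on it alone.
    ``global``: the whole dataset is balanced first and then folded,
    reproducing the balance-then-CV protocol order (duplicated minority
    rows can then appear on both sides of a fold split).  Predictions are
    pooled over folds before computing metrics.
    """
    if balanced not in ("within_fold", "global"):
        raise ValueError("balanced must be 'within_fold' or 'global'")
    work = balance_classes(ds, seed) if balanced == "global" else ds
    y = work.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} instances < {k} folds; use a smaller k"
        )
    X = work.X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    spec_seeded = replace(spec, seed=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if balanced == "within_fold":
            rng = np.random.default_rng(seed * 1000 + fold)
            tr = tr[_balance_indices(y[tr], rng)]
        est = build_estimator(spec_seeded, X.shape[1], classes.size)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
    cfg = {"classifier": spec.kind, "k": k, "balanced": balanced}
    return _metrics(y, y_pred, cfg, seed)


def person_specific_eval(
    ds: LabeledDataset,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 5,
    seed: int = 0,
):
    """Per-subject cross-validation; the headline number is the unweighted
    mean accuracy across retained subjects.

    A subject is retained only with at least ``max(k, 2 * n_classes)``
    instances and at least two instances of every class; within a subject
    the fold count shrinks to the smallest class count when necessary.
    Returns ``(EvalResult, per_subject_accuracy_dict)``.
    """
    subjects = np.unique(ds.subject_ids)
    per_subject = {}
    results = []
    n_classes = ds.n_classes
    for s in subjects:
        idx = np.flatnonzero(ds.subject_ids == s)
        sub = ds.subset(idx)
        _, counts = np.unique(sub.y, return_counts=True)
        if len(sub) < max(k, 2 * n_classes) or counts.size < 2 or counts.min() < 2:
            log.info("subject %s excluded from person-specific eval (%d instances)", s, len(sub))
            continue
        k_eff = min(k, int(counts.min()))
        res = run_cv(sub, spec, k=k_eff, balanced="within_fold", seed=seed)
        per_subject[str(s)] = res.accuracy
        results.append(res)
    if not results:
        raise ValueError("no subject has enough instances for person-specific evaluation")
    mean = EvalResult(
        accuracy=float(np.mean([r.accuracy for r in results])),
        f_measure=float(np.mean([r.f_measure for r in results])),
        precision=float(np.mean([r.precision for r in results])),
        recall=float(np.mean([r.recall for r in results])),
        confusion=sum(
            (np.zeros((3, 3), dtype=int) if r.confusion.shape != (3, 3) else r.confusion)
            for r in results
        ),
        classes=np.unique(ds.y),
        config={"classifier": spec.kind, "k": k, "mode": "person_specific"},
        seed=seed,
        per_subject=per_subject,
    )
    return mean, per_subject


def experiment_grid(
    datasets: dict,
    specs: Sequence[ClassifierSpec],
    k: int = 10,
    balanced: str = "within_fold",
    seed: int = 0,
) -> pd.DataFrame:
    """Cartesian product of named datasets x classifiers, one pooled-CV row
    per cell.

    ``datasets`` maps a condition name (e.g. a modality set, device filter
    or window length) to a :class:`LabeledDataset`; deterministic under
    ``seed``."""
    rows = []
    for (name, ds), spec in product(datasets.items(), specs):
        res = run_cv(ds, spec, k=k, balanced=balanced, seed=seed)
        rows.append(
            {
                "condition": name,
                "classifier": spec.kind,
                "n_instances": len(ds),
                "accuracy": res.accuracy,
                "f_measure": res.f_measure,
                "precision": res.precision,
                "recall": res.recall,
            }
        )
    return pd.DataFrame(rows)
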