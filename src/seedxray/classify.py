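"""Discriminant and nearest-neighbor classification with stratified CV.

Three classifiers are supported — linear discriminant analysis (LDA,
shared covariance), quadratic discriminant analysis (QDA, per-class
covariances) and KNN with k=5 — each behind a feature-standardization
step fitted on the training folds only.  Model assessment uses 10-fold
stratified cross-validation; the report carries the mean fold accuracy and
a 95% normal-approximation confidence band (mean +/- 1.96 * sd / sqrt(n)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .synthetic import ParameterError

#: ridge added to per-class covariances in QDA, relative to their scale
QDA_REGULARIZATION = 1e-6


@dataclass
class CVReport:
    """Cross-validation summary for one classifier (percent scale)."""

    classifier: str
    fold_accuracies: list[float]
    mean: float
    uci: float
    lci: float
    rng_seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _pipeline(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", estimator)])


def make_classifier(kind: str) -> Pipeline:
    """'lda', 'qda' or 'knn' -> unfitted standardize+classify pipeline."""
    kind = kind.lower()
    if kind == "lda":
        # svd solver tolerates singular pooled covariance (p >= n regime)
        return _pipeline(LinearDiscriminantAnalysis(solver="svd"))
    if kind == "qda":
        return _pipeline(QuadraticDiscriminantAnalysis(reg_param=QDA_REGULARIZATION))
    if kind == "knn":
        return _pipeline(KNeighborsClassifier(n_neighbors=5))
    raise ParameterError(f"unknown classifier {kind!r}")


def _check_training(features: pd.DataFrame, labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    values, counts = np.unique(y, return_counts=True)
    if values.size < 2 or counts.min() < 2:
        raise ParameterError("training needs >= 2 samples in each of >= 2 classes")
    return y


def fit_lda(features: pd.DataFrame, labels: Sequence) -> Pipeline:
    y = _check_training(features, labels)
    return make_classifier("lda").fit(features, y)


def fit_qda(features: pd.DataFrame, labels: Sequence) -> Pipeline:
    y = _check_training(features, labels)
    return make_classifier("qda").fit(features, y)


def fit_knn(features: pd.DataFrame, labels: Sequence, k: int = 5) -> Pipeline:
    y = _check_training(features, labels)
    if len(features) < k:
        raise ParameterError(f"KNN needs at least k={k} training samples")
    model = _pipeline(KNeighborsClassifier(n_neighbors=k))
    return model.fit(features, y)


def predict(model: Pipeline, features: pd.DataFrame) -> pd.DataFrame:
    """Class prediction with per-class posterior/score columns."""
    feature_names = list(model.feature_names_in_)
    missing = [n for n in feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"feature vector lacks {len(missing)} training features: {missing[:3]}...")
    x = features[feature_names]
    out = pd.DataFrame(index=features.index)
    out["predicted"] = model.predict(x)
    proba = model.predict_proba(x)
    for cls, col in zip(model.classes_, proba.T):
        out[f"p_{cls}"] = col
    return out


def confidence_interval(fold_accuracies: Sequence[float], z: float = 1.96) -> tuple[float, float]:
    """95% normal-approximation band over fold accuracies, clipped to [0, 100]."""
    acc = np.asarray(fold_accuracies, dtype=float)
    half = z * acc.std(ddof=1) / np.sqrt(acc.size) if acc.size > 1 else 0.0
    return float(np.clip(acc.mean() - half, 0, 100)), float(np.clip(acc.mean() + half, 0, 100))


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence,
    classifier: str | Pipeline = "lda",
    folds: int = 10,
    rng_seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV; deterministic given rng_seed."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ParameterError(
            f"smallest class has {counts.min()} samples, fewer than {folds} folds"
        )
    model = make_classifier(classifier) if isinstance(classifier, str) else classifier
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng_seed))
    accs = []
    for train_idx, test_idx in skf.split(features, y):
        fold_model = clone(model)
        fold_model.fit(features.iloc[train_idx], y[train_idx])
        pred = fold_model.predict(features.iloc[test_idx])
        accs.append(100.0 * float(np.mean(pred == y[test_idx])))
    lci, uci = confidence_interval(accs)
    name = classifier if isinstance(classifier, str) else type(model.named_steps["clf"]).__name__
    return CVReport(
        classifier=str(name),
        fold_accuracies=accs,
        mean=float(np.mean(accs)),
        uci=uci,
        lci=lci,
        rng_seed=int(rng_seed),
    )


def reference_pipeline(classifier: str = "lda", n_features: int = 25) -> Pipeline:
    """The default end-to-end classifier: per-fold Fisher top-k filter,
    standardization, then the chosen model.  Because the filter refits on
    each training fold, cross-validating this pipeline is free of feature-
    selection leakage (chance-level data scores at chance)."""
    from .selection import FisherScoreSelector

    base = make_classifier(classifier)
    return Pipeline(
        [("select", FisherScoreSelector(k=n_features))] + list(base.steps)
    )


def make_cv_evaluator(classifier: str = "lda", folds: int = 10, rng_seed: int = 0):
    """CV-mean-accuracy callable for the SFS wrapper."""

    def evaluator(features: pd.DataFrame, labels: Sequence) -> float:
        return cross_validate(features, labels, classifier, folds, rng_seed).mean

    return evaluator
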