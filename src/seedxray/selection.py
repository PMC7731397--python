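"""Fisher-score ranking and sequential forward selection (SFS).

The Fisher score of a feature for a two-class problem is

    J = (mu_1 - mu_2)^2 / (sigma_1^2 + sigma_2^2)

with population (ddof=0) class variances.  SFS greedily grows a feature
set, at each step adding the candidate that maximizes a cross-validated
wrapper accuracy; candidates are pre-pruned to the top ``candidate_pool``
features by Fisher score, and ties break by higher Fisher score, then by
name order, so traces are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features.vector import parse_feature_name
from .synthetic import ParameterError


@dataclass
class SelectionTrace:
    """Ordered selection result with the wrapper accuracy after each step."""

    features: list[str]
    cv_accuracy_at_step: list[float]
    fisher_scores: dict[str, float] = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        return int(np.argmax(self.cv_accuracy_at_step)) + 1

    @property
    def best_accuracy(self) -> float:
        return float(max(self.cv_accuracy_at_step))

    @property
    def best_features(self) -> list[str]:
        return self.features[: self.best_k]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                asdict(self) | {"best_k": self.best_k, "best_accuracy": self.best_accuracy},
                fh,
                indent=2,
            )


def fisher_score(features: pd.DataFrame, labels: Sequence) -> pd.Series:
    """Per-feature Fisher score J; requires both classes with >= 2 samples."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError(f"Fisher score needs exactly 2 classes, got {classes.size}")
    x1 = features.loc[y == classes[0]].to_numpy(dtype=float)
    x2 = features.loc[y == classes[1]].to_numpy(dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ParameterError("each class needs >= 2 samples")
    num = (x1.mean(axis=0) - x2.mean(axis=0)) ** 2
    den = x1.var(axis=0) + x2.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    return pd.Series(j, index=features.columns, name="fisher_score")


def sfs(
    features: pd.DataFrame,
    labels: Sequence,
    evaluator: Callable[[pd.DataFrame, Sequence], float],
    max_k: int = 60,
    candidate_pool: int = 150,
) -> SelectionTrace:
    """Greedy sequential forward selection wrapped around ``evaluator``.

    ``evaluator(feature_subframe, labels)`` must return an accuracy in
    percent.  Evaluation failures propagate with the step attached.
    """
    if max_k > features.shape[1]:
        raise ParameterError("max_k exceeds the number of features")
    scores = fisher_score(features, labels)
    ranked = scores.sort_values(ascending=False, kind="stable")
    # deterministic tie handling in the pool cut: score desc, then name asc
    order = sorted(ranked.index, key=lambda n: (-ranked[n], n))
    pool = order[: min(candidate_pool, len(order))]

    selected: list[str] = []
    accuracies: list[float] = []
    for step in range(max_k):
        best = None  # (acc, fisher, name)
        for cand in pool:
            if cand in selected:
                continue
            try:
                acc = float(evaluator(features[selected + [cand]], labels))
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(f"evaluator failed at step {step + 1} on {cand!r}") from exc
            key = (acc, scores[cand], _name_rank(cand))
            if best is None or key > best[0]:
                best = (key, cand, acc)
        if best is None:
            break
        selected.append(best[1])
        accuracies.append(best[2])
    return SelectionTrace(
        features=selected,
        cv_accuracy_at_step=accuracies,
        fisher_scores={n: float(scores[n]) for n in selected},
    )


class _name_rank(str):
    """Inverts string comparison so (acc, fisher, name) max-keys prefer the
    lexicographically smaller name on full ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


class FisherScoreSelector:
    """sklearn-style transformer keeping the top-k features by Fisher score.

    Fit on training folds only, so filter selection nests inside
    cross-validation without leaking label information from test folds.
    """

    def __init__(self, k: int = 25):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        frame = pd.DataFrame(X)
        scores = fisher_score(frame, y).to_numpy()
        k = min(self.k, X.shape[1])
        # stable: score desc, then column order
        self.support_ = np.argsort(-scores, kind="stable")[:k]
        self.scores_ = scores
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self


def summarize_selection(names: Sequence[str]) -> dict[str, dict[str, float]]:
    """Percentage composition of a selected feature list, by family and by
    enhancement set, rounded to one decimal (ties to even)."""
    if len(names) == 0:
        raise ParameterError("empty selection")
    fam_counts: dict[str, int] = {}
    set_counts: dict[str, int] = {}
    for name in names:
        family, set_letter = parse_feature_name(name)
        fam_counts[family] = fam_counts.get(family, 0) + 1
        set_counts[set_letter] = set_counts.get(set_letter, 0) + 1
    n = len(names)
    return {
        "family": {k: round(100.0 * v / n, 1) for k, v in sorted(fam_counts.items())},
        "set": {k: round(100.0 * v / n, 1) for k, v in sorted(set_counts.items())},
    }
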