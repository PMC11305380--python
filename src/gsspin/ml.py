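"""Random-forest spin-state models: training, 10-fold CV, importances.

The statistical model is a plain random-forest classifier over the
interpretable feature vectors (F_TM, F_CE, F_TM+CE). Cross-validation is
stratified by multiplicity so every fold sees every class; accuracy is the
unweighted fraction of correct predictions. Everything is deterministic for
a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateLabelsError, ValidationError

DEFAULT_HYPERPARAMS = {"n_estimators": 500, "max_depth": None, "n_jobs": 1}


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    confusion: pd.DataFrame          # rows true multiplicity, cols predicted
    seed: int
    feature_names: tuple[str, ...]

    @property
    def mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.fold_accuracies.std())

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean": self.mean,
            "std": self.std,
            "seed": self.seed,
            "features": list(self.feature_names),
            "confusion": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in self.confusion.to_dict(orient="index").items()
            },
        }


def _as_xy(features: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = tuple(f"x{i}" for i in range(x.shape[1]))
    y = np.asarray(labels)
    if len(x) != len(y):
        raise ValidationError("features and labels are misaligned")
    return x, y, names


def train_model(features: pd.DataFrame, labels, seed: int = 0,
                hyperparams: Optional[dict] = None) -> RandomForestClassifier:
    """Fit a random forest; raises on single-class labels."""
    x, y, names = _as_xy(features, labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    params = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    model = RandomForestClassifier(random_state=seed, **params)
    model.fit(x, y)
    model.gsspin_feature_names_ = names
    return model


def cross_validate(features: pd.DataFrame, labels, k: int = 10, seed: int = 0,
                   hyperparams: Optional[dict] = None) -> CVResult:
    """k-fold stratified cross-validation; every row is scored exactly once."""
    x, y, names = _as_xy(features, labels)
    if len(y) < k:
        raise ValidationError(f"need at least k={k} rows, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("cross-validation needs at least two classes")
    params = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    classes = np.unique(y)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    accuracies = []
    seen = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in splitter.split(x, y):
        model = RandomForestClassifier(random_state=seed, **params)
        model.fit(x[train_idx], y[train_idx])
        pred = model.predict(x[test_idx])
        accuracies.append(float(np.mean(pred == y[test_idx])))
        seen[test_idx] = True
        for t, p in zip(y[test_idx], pred):
            confusion.loc[t, p] += 1
    assert seen.all(), "CV folds failed to cover every row"
    return CVResult(fold_accuracies=np.array(accuracies), confusion=confusion,
                    seed=seed, feature_names=names)


def feature_importances(model: RandomForestClassifier) -> dict[str, float]:
    """Normalized impurity importances keyed by stable feature names."""
    if not hasattr(model, "estimators_"):
        raise ValidationError("model is not fitted")
    names = getattr(model, "gsspin_feature_names_",
                    tuple(f"x{i}" for i in range(model.n_features_in_)))
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return {name: float(v) for name, v in zip(names, imp)}


def per_metal_cross_validate(
    features: pd.DataFrame, labels, metals: Sequence[str],
    k: int = 10, seed: int = 0, hyperparams: Optional[dict] = None,
) -> dict[str, CVResult]:
    """One CVResult per metal symbol present in ``metals`` (row-aligned)."""
    metals = np.asarray(metals)
    out: dict[str, CVResult] = {}
    for metal in sorted(set(metals.tolist())):
        mask = metals == metal
        out[metal] = cross_validate(features[mask], np.asarray(labels)[mask],
                                    k=k, seed=seed, hyperparams=hyperparams)
    return out
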