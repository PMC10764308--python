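"""Linear-SVM classification of the 27-feature vectors.

Features are z-scored (statistics fit on training rows only) and fed to a
hard-margin-style linear SVM (hinge loss, penalty C = 1). Evaluation uses
stratified five-fold cross-validation (80% train / 20% test per fold) with a
seeded shuffle; accuracy is pooled over the five test folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InputError, SplitError, TrainingError
from .features import FEATURE_NAMES, FeatureVector27
from .retina_io import LABELS

#: label encoding: the decision value is positive for edematous
LABEL_MAP = {"non_edematous": -1, "edematous": +1}


@dataclass
class FeatureTable:
    sample_ids: list[str]
    X: np.ndarray  # (n, 27)
    labels: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise InputError(f"feature table must be n x {len(FEATURE_NAMES)}")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise InputError("duplicate sample ids")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise InputError(f"unknown labels: {bad}")

    def __len__(self):
        return self.X.shape[0]

    @classmethod
    def from_vectors(cls, ids, vectors: list[FeatureVector27], labels):
        return cls(list(ids), np.vstack([v.as_array() for v in vectors]), list(labels))


@dataclass
class TrainedModel:
    weights: np.ndarray  # in standardized feature space
    bias: float
    mean: np.ndarray
    std: np.ndarray
    used: np.ndarray  # boolean mask of features kept (std > 0)
    dropped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "mean": self.mean.tolist(),
                "std": self.std.tolist(),
                "used": self.used.astype(int).tolist(),
                "dropped": self.dropped,
                "feature_names": list(FEATURE_NAMES),
                "label_map": LABEL_MAP,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"], dtype=np.float64),
            bias=float(d["bias"]),
            mean=np.asarray(d["mean"], dtype=np.float64),
            std=np.asarray(d["std"], dtype=np.float64),
            used=np.asarray(d["used"], dtype=bool),
            dropped=list(d["dropped"]),
        )


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    pooled_accuracy: float
    predictions: list[str]  # aligned with the input table rows
    c_ede: int
    c_non: int
    n: int


def fit(table: FeatureTable, C: float = 1.0, seed: int = 0) -> TrainedModel:
    """Train the standardized linear SVM; deterministic given the seed."""
    y = np.array([LABEL_MAP[l] for l in table.labels])
    if len(np.unique(y)) < 2:
        raise TrainingError("training needs both classes")
    if not np.isfinite(table.X).all():
        raise InputError("non-finite feature values in training table")
    mean = table.X.mean(axis=0)
    std = table.X.std(axis=0)
    used = std > 0
    dropped = [FEATURE_NAMES[i] for i in np.nonzero(~used)[0]]
    Xs = (table.X[:, used] - mean[used]) / std[used]
    svm = SVC(kernel="linear", C=C, tol=1e-6, random_state=seed)
    svm.fit(Xs, y)
    weights = np.zeros(len(FEATURE_NAMES))
    weights[used] = svm.coef_.ravel()
    return TrainedModel(
        weights=weights,
        bias=float(svm.intercept_[0]),
        mean=mean,
        std=np.where(used, std, 1.0),
        used=used,
        dropped=dropped,
    )


def decision_value(model: TrainedModel, fv: np.ndarray) -> float:
    fv = np.asarray(fv, dtype=np.float64)
    if not np.isfinite(fv).all():
        raise InputError("non-finite feature vector")
    z = (fv - model.mean) / model.std
    return float(model.weights @ (z * model.used) + model.bias)


def predict(model: TrainedModel, fv) -> tuple[str, float]:
    """Predict one sample; a decision value of exactly 0 is resolved to
    non_edematous (conservative prescreening tie rule)."""
    if isinstance(fv, FeatureVector27):
        fv = fv.as_array()
    d = decision_value(model, fv)
    label = "edematous" if d > 0 else "non_edematous"
    return label, d


def cross_validate(table: FeatureTable, k: int = 5, seed: int = 0, C: float = 1.0) -> CVResult:
    """Stratified k-fold CV; every sample is tested exactly once."""
    n = len(table)
    if n < k:
        raise SplitError(f"cannot make {k} folds from {n} samples")
    y = np.array([LABEL_MAP[l] for l in table.labels])
    counts = np.bincount((y > 0).astype(int))
    if counts.min() < k:
        raise SplitError("a class has fewer samples than folds (stratification impossible)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds: list[str | None] = [None] * n
    fold_acc = []
    for train_idx, test_idx in skf.split(table.X, y):
        sub = FeatureTable(
            [table.sample_ids[i] for i in train_idx],
            table.X[train_idx],
            [table.labels[i] for i in train_idx],
        )
        model = fit(sub, C=C, seed=seed)
        correct = 0
        for i in test_idx:
            label, _ = predict(model, table.X[i])
            preds[i] = label
            correct += label == table.labels[i]
        fold_acc.append(correct / len(test_idx))
    c_ede = sum(
        1 for p, t in zip(preds, table.labels) if p == t == "edematous"
    )
    c_non = sum(
        1 for p, t in zip(preds, table.labels) if p == t == "non_edematous"
    )
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        pooled_accuracy=(c_ede + c_non) / n,
        predictions=list(preds),
        c_ede=c_ede,
        c_non=c_non,
        n=n,
    )
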