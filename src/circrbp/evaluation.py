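"""Classifier evaluation: accuracy, precision, ROC/AUC, and k-mer baselines.

The AUC is the rank-based (Mann-Whitney) statistic — the probability that a
random positive outscores a random negative, with ties counted one half —
which equals the trapezoidal area under the ROC curve built from all
distinct score thresholds. Baseline harness fits conventional learners
(MLP, SVM, random forest, logistic regression) on normalized 3-mer
composition features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from circrbp.encoding import kmer_features
from circrbp.sequence_io import SequenceRecord


@dataclass
class EvalReport:
    """Evaluation summary at a fixed decision threshold plus the full ROC."""

    accuracy: float
    precision: Optional[float]  # None when no positive predictions were made
    auc: float
    roc_points: list[tuple[float, float]]
    threshold: float
    n_pos: int
    n_neg: int

    def to_json(self, path: str | Path, extra: Optional[dict] = None) -> None:
        payload = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "precision_defined": self.precision is not None,
            "auc": self.auc,
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "roc_points": self.roc_points,
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _check_labels(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels, scores


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC with ties counted 1/2 (Mann-Whitney U / (n_pos*n_neg))."""
    labels, scores = _check_labels(np.asarray(labels), np.asarray(scores))
    ranks = rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> EvalReport:
    """Accuracy/precision at a threshold plus the all-thresholds ROC and AUC.

    Precision is reported as None (flagged, not 0) when the classifier makes
    no positive call at the threshold.
    """
    labels, scores = _check_labels(np.asarray(labels), np.asarray(scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    accuracy = (tp + tn) / labels.size
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return EvalReport(
        accuracy=float(accuracy),
        precision=precision,
        auc=roc_auc(labels, scores),
        roc_points=roc_points,
        threshold=threshold,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
    )


_LEARNERS = {
    "mlp": lambda seed: MLPClassifier(random_state=seed, max_iter=500),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
    "rf": lambda seed: RandomForestClassifier(random_state=seed),
    "logistic": lambda seed: LogisticRegression(random_state=seed, max_iter=1000),
}


def baseline_fit_predict(
    train_features: np.ndarray,
    train_labels: Sequence[int],
    test_features: np.ndarray,
    learner: str = "mlp",
    seed: int = 0,
) -> np.ndarray:
    """Fit an off-the-shelf learner on k-mer features; return positive-class scores.

    Supported learners: mlp, svm, rf, logistic (scikit-learn defaults,
    seeded). The learner internals are delegated, not specified.
    """
    if learner not in _LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {sorted(_LEARNERS)}")
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    clf = _LEARNERS[learner](seed)
    clf.fit(train_features, np.asarray(train_labels).astype(int))
    return clf.predict_proba(test_features)[:, 1]


def kmer_feature_matrix(records: Sequence[SequenceRecord], k: int = 3) -> np.ndarray:
    """Stack normalized k-mer vectors for a record list: (N, 4^k)."""
    return np.stack([kmer_features(r.seq, k) for r in records])
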