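"""Three-class linear discriminant-analysis tissue classifier.

Classifies 27-element window vectors as lesion, border-line or background.
Linear DA with a pooled within-class covariance is used: the discriminant
score of class c for a vector v is

    delta_c(v) = v' S^-1 mu_c - 1/2 mu_c' S^-1 mu_c + log pi_c

with S the pooled covariance ridge-regularized as S + gamma*I (near-constant
background windows make the raw 27x27 covariance rank-deficient), mu_c the
class mean and pi_c the class prior as fitted. Prediction is the argmax.

Training uses a seeded stratified 80/20 split; the held-out 20% metrics are
attached to the model. Stratified k-fold cross-validation (default k=5) is
available for robustness checks. Whole-volume classification labels every
voxel from its edge-replicated 3x3x3 window, yielding the three aligned
characteristic maps that feed the active-surface prior.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold, train_test_split

from petas3d.tissue_sampling import (
    BACKGROUND,
    LABEL_NAMES,
    LESION,
    SampleSet,
    _window_vectors,
)
from petas3d.volume_io import BinaryMask, SUVVolume

__all__ = ["DAModel", "ClassMaps", "train", "kfold_cv", "classify_volume", "roc_auc"]


@dataclass
class ClassMaps:
    """Aligned characteristic functions of the three tissue classes.

    At every voxel exactly one of the three maps equals 1 (they partition
    the grid).
    """

    lesion: BinaryMask
    border: BinaryMask
    background: BinaryMask

    def __post_init__(self) -> None:
        if not (self.lesion.grid == self.border.grid == self.background.grid):
            raise ValueError("class maps must share a grid")
        total = (
            self.lesion.values.astype(np.int64)
            + self.border.values
            + self.background.values
        )
        if not np.all(total == 1):
            raise ValueError("class maps must partition the grid (exactly one class per voxel)")

    @classmethod
    def from_labels(cls, grid, labels: np.ndarray) -> "ClassMaps":
        from petas3d.tissue_sampling import BORDER_LINE

        return cls(
            lesion=BinaryMask(grid, (labels == LESION).astype(np.uint8)),
            border=BinaryMask(grid, (labels == BORDER_LINE).astype(np.uint8)),
            background=BinaryMask(grid, (labels == BACKGROUND).astype(np.uint8)),
        )


@dataclass
class DAModel:
    """Fitted linear DA model over 27-vectors."""

    classes: np.ndarray  # label codes present, sorted
    means: np.ndarray  # (n_classes, 27)
    covariance: np.ndarray  # pooled within-class, (27, 27)
    priors: np.ndarray  # (n_classes,), sums to 1
    gamma: float
    holdout: dict | None = None  # metrics on the 20% test split
    _coef: np.ndarray | None = field(default=None, repr=False)
    _intercept: np.ndarray | None = field(default=None, repr=False)

    def _prepare(self) -> None:
        if self._coef is not None:
            return
        sigma = self.covariance + self.gamma * np.eye(self.covariance.shape[0])
        try:
            coef = linalg.solve(sigma, self.means.T, assume_a="pos").T
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "pooled covariance is singular; raise the ridge regularization gamma"
            ) from exc
        self._coef = coef
        self._intercept = -0.5 * np.einsum("ck,ck->c", self.means, coef) + np.log(self.priors)

    def decision_scores(self, vectors: np.ndarray) -> np.ndarray:
        """Per-class discriminant scores, shape (n, n_classes)."""
        self._prepare()
        return np.asarray(vectors, dtype=np.float64) @ self._coef.T + self._intercept

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(vectors)
        return self.classes[np.argmax(scores, axis=1)]

    def lesion_scores(self, vectors: np.ndarray) -> np.ndarray:
        """Lesion-vs-rest score: delta_lesion minus the best other class."""
        scores = self.decision_scores(vectors)
        li = int(np.where(self.classes == LESION)[0][0])
        others = np.delete(scores, li, axis=1)
        return scores[:, li] - others.max(axis=1)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "format": "petas3d-da-model",
            "window": "3x3x3, i-fastest flattening",
            "classes": self.classes.tolist(),
            "class_names": [LABEL_NAMES[int(c)] for c in self.classes],
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "gamma": self.gamma,
            "holdout": self.holdout,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "DAModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            classes=np.asarray(payload["classes"], dtype=np.int64),
            means=np.asarray(payload["means"], dtype=np.float64),
            covariance=np.asarray(payload["covariance"], dtype=np.float64),
            priors=np.asarray(payload["priors"], dtype=np.float64),
            gamma=float(payload["gamma"]),
            holdout=payload.get("holdout"),
        )


def _default_gamma(cov: np.ndarray) -> float:
    return 1e-6 * float(np.trace(cov)) / cov.shape[0]


def _fit(vectors: np.ndarray, labels: np.ndarray, gamma: float | None) -> DAModel:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    d = vectors.shape[1]
    means = np.stack([vectors[labels == c].mean(axis=0) for c in classes])
    priors = np.array([(labels == c).mean() for c in classes])
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        xc = vectors[labels == c] - means[i]
        scatter += xc.T @ xc
    cov = scatter / max(len(labels) - len(classes), 1)
    if gamma is None:
        gamma = _default_gamma(cov)
    return DAModel(classes=classes, means=means, covariance=cov, priors=priors, gamma=float(gamma))


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Accuracy plus lesion-vs-rest sensitivity/specificity."""
    acc = float(np.mean(y_true == y_pred))
    pos = y_true == LESION
    out = {"accuracy": acc, "n": int(len(y_true))}
    if pos.any():
        out["sensitivity"] = float(np.mean(y_pred[pos] == LESION))
    if (~pos).any():
        out["specificity"] = float(np.mean(y_pred[~pos] != LESION))
    return out


def train(
    samples: SampleSet,
    gamma: float | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> DAModel:
    """Fit linear DA on a seeded stratified 80/20 split of ``samples``.

    The model is fitted on the 80% partition; accuracy and lesion-vs-rest
    sensitivity/specificity on the held-out 20% are stored in
    ``model.holdout``. Requires more samples than the 27 feature dimensions
    after the split. ``test_fraction=0`` fits on every sample (no holdout).
    """
    X, y = samples.vectors, samples.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes present")
    if len(y) * (1 - test_fraction) < X.shape[1] + 1:
        raise ValueError(
            f"need more samples than dimensions after the split, got {len(y)}"
        )
    if test_fraction == 0:
        return _fit(X, y, gamma)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    model = _fit(X_tr, y_tr, gamma)
    model.holdout = _metrics(y_te, model.predict(X_te))
    return model


def kfold_cv(
    samples: SampleSet, k: int = 5, gamma: float | None = None, seed: int = 0
) -> dict:
    """Stratified k-fold cross-validation of the DA classifier.

    Each fold serves once as validation. Returns per-fold accuracy,
    lesion-vs-rest sensitivity and specificity, plus their mean and std.
    """
    X, y = samples.vectors, samples.labels
    _, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(X, y):
        model = _fit(X[tr], y[tr], gamma)
        folds.append(_metrics(y[va], model.predict(X[va])))
    out: dict = {"k": k, "folds": folds}
    for key in ("accuracy", "sensitivity", "specificity"):
        vals = [f[key] for f in folds if key in f]
        if vals:
            out[f"mean_{key}"] = float(np.mean(vals))
            out[f"std_{key}"] = float(np.std(vals))
    return out


def classify_volume(model: DAModel, vol: SUVVolume, chunk: int = 1 << 16) -> ClassMaps:
    """Label every voxel of ``vol`` from its edge-replicated 3x3x3 window.

    The volume border is edge-replicated so boundary voxels also receive a
    window; the resulting lesion/border/background maps partition the grid.
    """
    padded = np.pad(vol.values, 1, mode="edge")
    vectors = _window_vectors(padded)
    labels = np.empty(len(vectors), dtype=np.int64)
    for start in range(0, len(vectors), chunk):
        labels[start : start + chunk] = model.predict(vectors[start : start + chunk])
    return ClassMaps.from_labels(vol.grid, labels.reshape(vol.grid.shape))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for lesion-vs-rest scores.

    Equals the probability that a random positive scores above a random
    negative, with ties counted 1/2 (rank / Mann-Whitney formulation,
    identical to the trapezoidal ROC integral).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)
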