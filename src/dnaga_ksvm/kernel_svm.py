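"""Soft-margin RBF-kernel SVM and confusion-matrix metrics.

The classifier solves the usual soft-margin problem

    min  1/2 ||w||^2 + C sum_i xi_i
    s.t. y_i (w.phi(x_i) + b) >= 1 - xi_i,  xi_i >= 0,

in the dual, under the Gaussian kernel K(x, y) = exp(-sigma ||x - y||^2).
Note the width convention: sigma multiplies the squared distance (a
gamma-style parameter), so larger sigma means a narrower kernel.  Features
are standardized per column (statistics from the training data only)
before the kernel is evaluated, since squared Euclidean distances are
scale-sensitive.

The dual is solved by libsvm via scikit-learn; this module owns the
estimator surface, the width convention, validation, serialization and the
confusion-matrix metrics.  The returned model satisfies the KKT box
constraint 0 <= alpha_i <= C and the equality constraint
sum_i alpha_i y_i = 0, which the tests verify directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

NEGATIVE, POSITIVE = -1, 1  # benign, malignant


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """K(x, y) = exp(-sigma ||x - y||^2); sigma = 0 degenerates to 1."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if sigma < 0:
        raise ValueError("kernel width sigma must be >= 0")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-sigma * d2))


def gram_matrix(X: np.ndarray, sigma: float) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-sigma * d2)


class KernelSVC(BaseEstimator, ClassifierMixin):
    """Soft-margin SVM with the exp(-sigma d^2) Gaussian kernel.

    Parameters
    ----------
    C : float
        Penalty coefficient on the slack variables; larger C punishes
        misclassification harder.
    sigma : float
        Kernel width multiplier (gamma convention).
    standardize : bool
        Standardize columns using training-set statistics before the
        kernel is evaluated.
    tol : float
        Dual-solver stopping tolerance; kept well below the 1e-3 KKT
        residual contract.
    """

    def __init__(self, C: float = 100.0, sigma: float = 1.0,
                 standardize: bool = True, tol: float = 1e-6):
        self.C = C
        self.sigma = sigma
        self.standardize = standardize
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be > 0")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"exactly two classes required for training, got {classes}"
            )
        if not set(classes) <= {NEGATIVE, POSITIVE}:
            raise ValueError("labels must be in {-1, +1}")
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0  # constant columns carry no information
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        self._svc = SVC(C=self.C, kernel="rbf", gamma=self.sigma,
                        tol=self.tol)
        self._svc.fit(Xs, y)
        self.support_vectors_ = self._svc.support_vectors_
        self.dual_coef_ = self._svc.dual_coef_[0]  # alpha_i * y_i
        self.intercept_ = float(self._svc.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def _transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.scale_

    def decision_function(self, X) -> np.ndarray:
        """sum_i alpha_i y_i K(s_i, x) + b."""
        check_is_fitted(self, "dual_coef_")
        Xs = self._transform(X)
        sq_sv = np.sum(self.support_vectors_ ** 2, axis=1)
        sq_x = np.sum(Xs**2, axis=1)
        d2 = sq_x[:, None] + sq_sv[None, :] - 2.0 * Xs @ self.support_vectors_.T
        np.maximum(d2, 0.0, out=d2)
        return np.exp(-self.sigma * d2) @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Labels in {-1, +1}; a zero decision value breaks to +1."""
        return np.where(self.decision_function(X) >= 0, POSITIVE, NEGATIVE)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "dual_coef_")
        return {
            "C": self.C,
            "sigma": self.sigma,
            "standardize": self.standardize,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "bias": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSVC":
        model = cls(C=d["C"], sigma=d["sigma"], standardize=d["standardize"])
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        model.intercept_ = float(d["bias"])
        model.classes_ = np.array([NEGATIVE, POSITIVE])
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "KernelSVC":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train(X, y, C: float, sigma: float) -> KernelSVC:
    """Functional wrapper over :class:`KernelSVC`."""
    return KernelSVC(C=C, sigma=sigma).fit(X, y)


def _pct(num: int, den: int) -> float | None:
    """Percentage rounded half-up to 2 decimals, as printed in reports."""
    if den == 0:
        return None
    pct = Decimal(num) / Decimal(den) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with malignant (+1) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def success_cases(self) -> int:
        return self.tp + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return self.success_cases / self.total if self.total else None

    @property
    def sensitivity_pct(self) -> float | None:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity_pct(self) -> float | None:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def accuracy_pct(self) -> float | None:
        return _pct(self.success_cases, self.total)


def confusion_and_metrics(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == POSITIVE
    pos_p = y_pred == POSITIVE
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def metrics_to_csv(cm: ConfusionMatrix, path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["TP", "FP", "FN", "TN",
                    "sensitivity_pct", "specificity_pct", "accuracy_pct"])
        w.writerow([cm.tp, cm.fp, cm.fn, cm.tn,
                    cm.sensitivity_pct, cm.specificity_pct, cm.accuracy_pct])
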