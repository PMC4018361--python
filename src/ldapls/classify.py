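"""Bayes-rule linear classifier on projected scores, and imbalance metrics.

Every dimension-reduction method under comparison feeds its d-dimensional
scores to the same classifier: class-conditional Gaussians with a pooled
(shared) covariance and empirical priors — the canonical linear Bayes
rule.  A ``naive`` switch restricts the pooled covariance to its diagonal.

Metrics are accuracy, G-Mean = sqrt(TPR * TNR) and the F-Value
(harmonic mean of precision and recall of the +1 class); the latter two
remain informative on imbalanced data where accuracy alone saturates.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


class GaussianLinearClassifier(ClassifierMixin, BaseEstimator):
    """Linear Gaussian discriminant with pooled covariance.

    The decision function for scores ``s`` is

        g(s) = (mu2 - mu1)^T S^-1 s - 1/2 (mu2 + mu1)^T S^-1 (mu2 - mu1)
               + log(pi2 / pi1)

    with ``g > 0`` predicting the +1 class.  A ridge of
    ``ridge * trace(S)/d`` is added (and logged) if the pooled covariance
    is numerically singular.
    """

    def __init__(self, naive: bool = False, ridge: float = 1e-8):
        self.naive = naive
        self.ridge = ridge

    def fit(self, S, y):
        S = np.asarray(S, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
        y = np.asarray(y)
        n, d = S.shape
        neg, pos = S[y == -1], S[y == 1]
        n1, n2 = neg.shape[0], pos.shape[0]
        if n1 == 0 or n2 == 0:
            raise ValueError("both classes must be present to fit the classifier")
        self.classes_ = np.array([-1, 1])
        self.means_ = np.vstack([neg.mean(axis=0), pos.mean(axis=0)])
        self.priors_ = np.array([n1 / n, n2 / n])
        dof = max(n - 2, 1)
        R1 = neg - self.means_[0]
        R2 = pos - self.means_[1]
        cov = (R1.T @ R1 + R2.T @ R2) / dof
        if self.naive:
            cov = np.diag(np.diag(cov))
        self.ridge_applied_ = 0.0
        jitter = self.ridge * max(np.trace(cov) / d, 0.0)
        if jitter == 0.0:
            jitter = 1e-12
        for attempt in range(12):
            try:
                np.linalg.cholesky(cov + np.eye(d) * self.ridge_applied_)
                break
            except np.linalg.LinAlgError:
                self.ridge_applied_ = jitter * 10**attempt
        else:
            raise np.linalg.LinAlgError("pooled covariance could not be regularized")
        if self.ridge_applied_:
            logger.info("added ridge %.3g to singular pooled covariance", self.ridge_applied_)
        cov = cov + np.eye(d) * self.ridge_applied_
        self.covariance_ = cov
        diff = self.means_[1] - self.means_[0]
        self.coef_ = np.linalg.solve(cov, diff)
        self.intercept_ = float(
            -0.5 * (self.means_[1] + self.means_[0]) @ self.coef_
            + math.log(self.priors_[1] / self.priors_[0])
        )
        self.n_features_in_ = d
        return self

    def decision_function(self, S) -> np.ndarray:
        check_is_fitted(self, "coef_")
        S = np.asarray(S, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
        if S.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: {S.shape[1]} != {self.n_features_in_}"
            )
        return S @ self.coef_ + self.intercept_

    def predict(self, S) -> np.ndarray:
        return np.where(self.decision_function(S) > 0, 1, -1)


def fit_classifier(scores, y, naive: bool = False) -> GaussianLinearClassifier:
    """Functional wrapper over :class:`GaussianLinearClassifier`."""
    return GaussianLinearClassifier(naive=naive).fit(scores, y)


def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy, G-Mean and F-Value for -1/+1 labels.

    Returns a dict with keys ``acc``, ``gmean``, ``fvalue`` and
    ``degenerate``.  Conventions for empty denominators: a class absent
    from ``y_true`` makes G-Mean NaN (flagged, excluded from protocol
    means); no predicted positives makes the F-Value 0 (flagged).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == -1) & (y_pred == -1)).sum())
    fp = int(((y_true == -1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == -1)).sum())
    n = y_true.size
    acc = (tp + tn) / n
    degenerate = False

    if tp + fn == 0 or tn + fp == 0:  # a class absent from y_true
        gmean = float("nan")
        degenerate = True
    else:
        tpr = tp / (tp + fn)
        tnr = tn / (tn + fp)
        gmean = math.sqrt(tpr * tnr)

    if tp + fn == 0:
        fvalue = float("nan")
        degenerate = True
    elif tp + fp == 0:  # no predicted positives: precision undefined
        fvalue = 0.0
        degenerate = True
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        fvalue = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
    return {"acc": acc, "gmean": gmean, "fvalue": fvalue, "degenerate": degenerate}
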