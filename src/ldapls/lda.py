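"""Two-class linear discriminant analysis solved through an SVD pseudo-inverse.

For two classes the between-class scatter ``S_B = (m1-m2)(m1-m2)^T`` has
rank one, so the Rayleigh-quotient maximizer reduces to the closed form

    w  ∝  S_W^+ (m2 - m1),

where ``S_W^+`` is the Moore-Penrose pseudo-inverse of the within-class
scatter.  The pseudo-inverse route keeps the direction well-defined in the
small-sample regime (k > n, singular ``S_W``) that high-dimensional
spectra produce.  Rather than factoring the k x k scatter directly, the
implementation takes the thin SVD of the class-centered data matrix C
(``S_W = C^T C``), which is exact and much cheaper when k >> n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import DegenerateLabelsError, LabeledDataset

#: relative singular-value cutoff for the S_W pseudo-inverse
SVD_RTOL = 1e-10


class NoWithinClassVariationError(ValueError):
    """S_W is exactly zero: every sample equals its class mean."""


class DegenerateDirectionError(ValueError):
    """The mean difference lies entirely in the truncated null space."""


def _split_xy(X, y=None):
    if isinstance(X, LabeledDataset):
        return X.X, X.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    return X, y


def class_means(X, y=None) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic class centers ``(m1, m2)`` for the -1 and +1 class."""
    X, y = _split_xy(X, y)
    m = []
    for label in (-1, 1):
        rows = X[y == label]
        if rows.shape[0] == 0:
            raise DegenerateLabelsError(f"degenerate labels: class {label} is empty")
        m.append(rows.mean(axis=0))
    return m[0], m[1]


@dataclass
class ScatterMatrices:
    """Within- and between-class scatter of a two-class dataset.

    ``S_W`` is the raw (unnormalized) sum of class-centered outer products;
    ``S_B`` the plain outer product of the class-mean difference.  Any
    positive scaling of either only rescales the discriminant direction,
    which is re-normalized downstream.
    """

    S_W: np.ndarray
    S_B: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    counts: tuple[int, int]


def scatter_matrices(X, y=None) -> ScatterMatrices:
    """Compute ``S_W = sum_i sum_{x in i} (x-m_i)(x-m_i)^T`` and
    ``S_B = (m1-m2)(m1-m2)^T``."""
    X, y = _split_xy(X, y)
    m1, m2 = class_means(X, y)
    C1 = X[y == -1] - m1
    C2 = X[y == 1] - m2
    S_W = C1.T @ C1 + C2.T @ C2
    diff = (m1 - m2)[:, None]
    S_B = diff @ diff.T
    n1 = int((y == -1).sum())
    n2 = int((y == 1).sum())
    return ScatterMatrices(S_W=S_W, S_B=S_B, m1=m1, m2=m2, counts=(n1, n2))


def _within_centered(X, y) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered by their own class mean, and the mean difference m2-m1."""
    m1, m2 = class_means(X, y)
    C = X.copy()
    C[y == -1] -= m1
    C[y == 1] -= m2
    return C, m2 - m1


def lda_direction(X, y=None, rtol: float = SVD_RTOL) -> np.ndarray:
    """Unit discriminant direction ``w ∝ S_W^+ (m2 - m1)``.

    The pseudo-inverse is evaluated through the thin SVD of the
    class-centered matrix; singular values of S_W below ``rtol`` times the
    largest are treated as zero.  The sign is fixed so that the projected
    mean of the +1 class is the larger one.
    """
    X, y = _split_xy(X, y)
    C, delta = _within_centered(X, y)
    if not np.any(C):
        raise NoWithinClassVariationError(
            "no within-class variation: every sample equals its class mean"
        )
    # S_W = V diag(s**2) V^T with C = U diag(s) V^T
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    ev = s**2
    keep = ev > rtol * ev[0]
    w = Vt[keep].T @ ((Vt[keep] @ delta) / ev[keep])
    norm = np.linalg.norm(w)
    if norm <= 0 or not np.isfinite(norm):
        raise DegenerateDirectionError(
            "degenerate direction: class-mean difference lies in the "
            f"truncated null space (rank kept {int(keep.sum())}/{len(ev)}, "
            f"|m2-m1| = {np.linalg.norm(delta):.3g})"
        )
    w = w / norm
    if w @ delta < 0:  # orient toward the +1 class
        w = -w
    return w


class LinearDiscriminantDirection(TransformerMixin, BaseEstimator):
    """Projection onto the two-class LDA direction.

    Fitted attributes
    -----------------
    direction_ : ndarray of shape (k,)
        Unit discriminant direction, oriented so the +1 class projects high.
    mean_ : ndarray of shape (k,)
        Training column means; new samples are centered before projection.
    means_ : tuple of ndarray
        Class centers ``(m1, m2)``.
    """

    def __init__(self, rtol: float = SVD_RTOL):
        self.rtol = rtol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.mean_ = X.mean(axis=0)
        self.means_ = class_means(X, y)
        self.direction_ = lda_direction(X, y, rtol=self.rtol)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "direction_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: {X.shape[1]} != {self.n_features_in_}"
            )
        return (X - self.mean_) @ self.direction_[:, None]
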