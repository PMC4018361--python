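"""NIPALS partial least squares regression.

One latent component at a time, the classical alternating iteration

    w ∝ X^T u   (normalize)      t = X w
    q ∝ Y^T t   (normalize)      u = Y q

is run to convergence on ``t``; then the loadings ``p = X^T t / t^T t``,
inner coefficient ``b = u^T t / t^T t`` are recorded and both blocks are
deflated, ``X <- X - t p^T`` and ``Y <- Y - b t q^T``, before the next
component.  For a single-column Y the loop converges after one pass with
``w ∝ X^T y`` exactly.  The assembled regression coefficients are

    B = W (P^T W)^{-1} diag(b) Q^T,

the matrix with ``Yc_hat = Xc B``.  Data are column-centered internally
(means learned in ``fit`` and reused for prediction).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import CenteringTransform, fit_center

#: relative convergence tolerance on the score vector t
NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
#: Frobenius-norm fraction below which the X residual counts as exhausted
RANK_EPS = 1e-10


class ZeroWeightError(ValueError):
    """X^T u vanished: no covariance left between the blocks."""


def nipals_component(
    Xc: np.ndarray,
    Yc: np.ndarray,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
):
    """Extract one PLS component from centered blocks.

    Returns ``(w, t, p, q, u, b_inner, n_iter)``.  The sign of the
    component is fixed so that the largest-magnitude entry of ``w`` is
    positive (NIPALS signs are otherwise arbitrary).
    """
    Xc = np.asarray(Xc, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    if Yc.ndim == 1:
        Yc = Yc[:, None]
    # start from the Y column with the largest variance
    u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
    if not np.any(u):
        u = Yc[:, 0].copy()
    t_old = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = Xc.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ZeroWeightError("zero weight: X^T u vanished")
        w /= nw
        t = Xc @ w
        q = Yc.T @ t
        nq = np.linalg.norm(q)
        if nq == 0:
            raise ZeroWeightError("zero weight: Y^T t vanished")
        q /= nq
        u = Yc @ q
        if t_old is not None:
            denom = np.linalg.norm(t_old)
            if denom == 0 or np.linalg.norm(t - t_old) <= tol * denom:
                break
        t_old = t
    else:
        warnings.warn(
            f"NIPALS did not converge in {max_iter} iterations; "
            "returning current iterate",
            RuntimeWarning,
        )
    tt = t @ t
    if tt == 0:
        raise ZeroWeightError("zero weight: score vector t vanished")
    p = Xc.T @ t / tt
    b_inner = (u @ t) / tt
    # sign convention: largest-|entry| of w positive
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w, t, p, q, u = -w, -t, -p, -q, -u
    return w, t, p, q, u, b_inner, n_iter


class NipalsPLS(RegressorMixin, TransformerMixin, BaseEstimator):
    """PLS regression fitted by the NIPALS iteration.

    Parameters
    ----------
    n_components : int
        Number of latent variables ``a`` to extract.
    tol, max_iter : convergence control for each component.
    scale : bool
        Optional unit-variance column scaling (off by default; the model
        only presumes centering).

    Fitted attributes (shapes use k features, m targets, a components)
    -----------------
    x_weights_ : (k, a)   unit-norm NIPALS weights W
    x_scores_ : (n, a)    scores T (mutually orthogonal)
    x_loadings_ : (k, a)  loadings P
    y_scores_ : (n, a)    scores U
    y_loadings_ : (m, a)  loadings Q (unit-norm columns)
    inner_coefs_ : (a,)   inner regression coefficients b
    coef_ : (k, m)        assembled regression coefficients B
    x_residual_, y_residual_ : deflation residuals E and H
    n_iter_ : list of per-component iteration counts
    """

    def __init__(
        self,
        n_components: int = 2,
        tol: float = NIPALS_TOL,
        max_iter: int = NIPALS_MAX_ITER,
        scale: bool = False,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, k = X.shape
        if not 1 <= self.n_components <= min(n - 1, k):
            raise ValueError(
                f"n_components must be in [1, min(n-1, k)] = "
                f"[1, {min(n - 1, k)}], got {self.n_components}"
            )
        self.x_center_: CenteringTransform = fit_center(X, scale=self.scale)
        self.y_center_: CenteringTransform = fit_center(Y)
        Xc = self.x_center_.apply(X)
        Yc = self.y_center_.apply(Y)
        x_norm0 = np.linalg.norm(Xc)

        W, T, P, Q, U, b, iters = [], [], [], [], [], [], []
        for _ in range(self.n_components):
            if np.linalg.norm(Xc) <= RANK_EPS * max(x_norm0, 1.0):
                warnings.warn(
                    f"X residual exhausted after {len(W)} components; "
                    f"requested {self.n_components}",
                    RuntimeWarning,
                )
                break
            w, t, p, q, u, b_inner, n_it = nipals_component(
                Xc, Yc, tol=self.tol, max_iter=self.max_iter
            )
            W.append(w)
            T.append(t)
            P.append(p)
            Q.append(q)
            U.append(u)
            b.append(b_inner)
            iters.append(n_it)
            Xc = Xc - np.outer(t, p)
            Yc = Yc - b_inner * np.outer(t, q)

        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.column_stack(Q)
        self.y_scores_ = np.column_stack(U)
        self.inner_coefs_ = np.asarray(b)
        self.n_iter_ = iters
        self.n_components_ = len(W)
        self.x_residual_ = Xc
        self.y_residual_ = Yc
        self.n_features_in_ = k
        self.coef_ = self._assemble_coefficients()
        # score rotation: T = Xc R with R = W (P^T W)^{-1}
        self._rotation = self.x_weights_ @ self._ptw_inv()
        return self

    def _ptw_inv(self) -> np.ndarray:
        PtW = self.x_loadings_.T @ self.x_weights_
        cond = np.linalg.cond(PtW)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"P^T W is numerically singular (cond={cond:.3g}) at "
                f"component {self.n_components_}"
            )
        return np.linalg.inv(PtW)

    def _assemble_coefficients(self) -> np.ndarray:
        """B = W (P^T W)^{-1} diag(b) Q^T, the matrix with Yc_hat = Xc B."""
        return (
            self.x_weights_
            @ self._ptw_inv()
            @ np.diag(self.inner_coefs_)
            @ self.y_loadings_.T
        )

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the latent scores T."""
        check_is_fitted(self, "coef_")
        Xc = self.x_center_.apply(np.asarray(X, dtype=float))
        return Xc @ self._rotation

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xc = self.x_center_.apply(np.asarray(X, dtype=float))
        return self.y_center_.revert(Xc @ self.coef_)

    def to_dict(self) -> dict:
        """Plain-text serializable dump of the fitted model."""
        check_is_fitted(self, "coef_")
        return {
            "kind": "nipals_pls",
            "n_components": self.n_components_,
            "x_mean": self.x_center_.column_means.tolist(),
            "y_mean": self.y_center_.column_means.tolist(),
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "inner_coefs": self.inner_coefs_.tolist(),
            "coef": self.coef_.tolist(),
        }


def fit_pls(X, Y, n_lv: int, **kwargs) -> NipalsPLS:
    """Functional wrapper: fit a :class:`NipalsPLS` with ``n_lv`` components."""
    return NipalsPLS(n_components=n_lv, **kwargs).fit(X, Y)


def regression_coefficients(model: NipalsPLS) -> np.ndarray:
    """The assembled ``k x m`` coefficient matrix B of a fitted model."""
    check_is_fitted(model, "coef_")
    return model.coef_


def pls_predict(model: NipalsPLS, X_new) -> np.ndarray:
    """Predict responses for new samples: ``(X - mean_X) B + mean_Y``."""
    return model.predict(X_new)
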