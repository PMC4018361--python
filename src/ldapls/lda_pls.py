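"""LDA-PLS and ex-LDA-PLS supervised projection directions.

LDA-PLS corrects the two-class LDA direction with PLS: the LDA projection
values ``c = Xc w_lda`` are used as the regression target of a NIPALS-PLS
fit on ``Xc``, and the PLS coefficient vector ``B`` becomes the corrected
discriminant direction.  With few latent variables B is a smoothed/rotated
version of ``w_lda`` (one LV gives ``B ∝ Xc^T Xc w_lda``); with a full set
of latent variables the regression of ``c`` on ``Xc`` is exact and B
collapses back onto ``w_lda``.  Successive components are obtained by
rank-one deflation of ``Xc`` along the extracted score.

ex-LDA-PLS adds a continuous control between the two endpoints: the final
direction is the normalized convex blend

    w(λ) = normalize( (1-λ) ŵ_lda + λ B̂ ),        λ ∈ [0, 1],

with both inputs unit-normalized (their raw scales differ by an arbitrary
proportionality constant).  λ is chosen by accuracy on a held-out half of
the training set, traversing the grid 0, 0.001, ..., 1 once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .dataset import fit_center
from .lda import SVD_RTOL, DegenerateDirectionError, lda_direction
from .pls import NipalsPLS

#: λ grid step of the ex-LDA-PLS traversal
LAMBDA_STEP = 1e-3
#: residual Frobenius norm (relative) below which deflation stops
DEFLATION_EPS = 1e-10


class DegenerateBlendError(ValueError):
    """(1-λ)w + λB vanished: inputs antiparallel at an interior λ."""


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise ValueError(f"{what} must be a nonzero finite vector")
    return v / n


@dataclass
class ExLDAPLSDirection:
    """A λ-blended direction between LDA and LDA-PLS."""

    lam: float
    w_combined: np.ndarray
    w_lda: np.ndarray
    b_ldapls: np.ndarray


def combine_ex(w_lda, b_ldapls, lam: float) -> ExLDAPLSDirection:
    """Blend the (normalized) LDA direction and LDA-PLS coefficient vector.

    ``lam = 0`` returns the LDA direction, ``lam = 1`` the LDA-PLS one.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    w_hat = _unit(w_lda, "w_lda")
    b_hat = _unit(b_ldapls, "B_ldapls")
    if lam == 0.0 or lam == 1.0:  # exact endpoint semantics
        chosen = w_hat if lam == 0.0 else b_hat
        return ExLDAPLSDirection(
            lam=lam, w_combined=chosen, w_lda=w_hat, b_ldapls=b_hat
        )
    mix = (1.0 - lam) * w_hat + lam * b_hat
    norm = np.linalg.norm(mix)
    if norm < 1e-12:
        raise DegenerateBlendError(
            f"degenerate blend: inputs antiparallel at lambda={lam}"
        )
    return ExLDAPLSDirection(
        lam=lam, w_combined=mix / norm, w_lda=w_hat, b_ldapls=b_hat
    )


class LDAPLS(TransformerMixin, BaseEstimator):
    """LDA-PLS projection with one or more deflation components.

    Parameters
    ----------
    n_components : int
        Number of outer LDA-PLS components.
    n_lv : int
        Latent-variable count of the inner PLS regression.
    deflation : {"pls", "lda"}
        Direction of the rank-one deflation: along the score of the
        extracted coefficient vector ``t = X B / |X B|`` (default), or
        along the LDA score ``X w_lda`` (sensitivity switch).
    rtol : float
        Singular-value cutoff of the inner LDA pseudo-inverse.

    Fitted attributes
    -----------------
    directions_lda_ : (k, C)  per-component LDA directions w_lda^(i)
    coefs_ : (k, C)           per-component PLS coefficient vectors B^(i)
    deflation_scores_ : (n, C) unit deflation scores t^(i) (orthogonal)
    deflation_loadings_ : (k, C) loadings p^(i)
    score_norms_ : (C,)       |X^(i) B^(i)| used to normalize each score
    mean_ : (k,)              training column means
    """

    def __init__(
        self,
        n_components: int = 1,
        n_lv: int = 1,
        deflation: str = "pls",
        rtol: float = SVD_RTOL,
    ):
        self.n_components = n_components
        self.n_lv = n_lv
        self.deflation = deflation
        self.rtol = rtol

    def fit(self, X, y):
        if self.n_components < 1 or self.n_lv < 1:
            raise ValueError("n_components and n_lv must be >= 1")
        if self.deflation not in ("pls", "lda"):
            raise ValueError(f"unknown deflation mode {self.deflation!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.center_ = fit_center(X)
        Xr = self.center_.apply(X)
        norm0 = np.linalg.norm(Xr)

        W_lda, B, T, P, norms, defl_dirs = [], [], [], [], [], []
        for i in range(self.n_components):
            if np.linalg.norm(Xr) <= DEFLATION_EPS * max(norm0, 1.0):
                warnings.warn(
                    f"residual exhausted after {i} components; "
                    f"requested {self.n_components}",
                    RuntimeWarning,
                )
                break
            try:
                w_lda = lda_direction(Xr, y, rtol=self.rtol)
            except DegenerateDirectionError:
                if i == 0:
                    raise
                warnings.warn(
                    f"LDA degenerate on residual at component {i + 1}; "
                    "stopping early",
                    RuntimeWarning,
                )
                break
            c = Xr @ w_lda
            n_lv = min(self.n_lv, Xr.shape[0] - 1, Xr.shape[1])
            pls = NipalsPLS(n_components=n_lv).fit(Xr, c)
            b_vec = pls.coef_[:, 0]
            s = Xr @ b_vec
            s_norm = np.linalg.norm(s)
            if s_norm < 1e-12:
                if i == 0:
                    raise DegenerateDirectionError(
                        "degenerate direction: X B vanished on first component"
                    )
                warnings.warn("X B vanished; stopping early", RuntimeWarning)
                break
            if self.deflation == "pls":
                defl_dir, defl_norm = b_vec, s_norm
            else:
                t_raw = Xr @ w_lda
                defl_dir, defl_norm = w_lda, np.linalg.norm(t_raw)
            t = (Xr @ defl_dir) / defl_norm
            p = Xr.T @ t
            W_lda.append(w_lda)
            B.append(b_vec)
            T.append(t)
            P.append(p)
            norms.append(defl_norm)
            defl_dirs.append(defl_dir)
            Xr = Xr - np.outer(t, p)

        self.directions_lda_ = np.column_stack(W_lda)
        self.coefs_ = np.column_stack(B)
        self.deflation_scores_ = np.column_stack(T)
        self.deflation_loadings_ = np.column_stack(P)
        self.score_norms_ = np.asarray(norms)
        self._deflation_dirs = np.column_stack(defl_dirs)
        self.n_components_ = len(B)
        self.n_features_in_ = X.shape[1]
        return self

    def _staged_scores(self, X, directions: np.ndarray) -> np.ndarray:
        """Project through the stored deflation stages onto ``directions``.

        Stage residuals of new data are reconstructed with the stored
        loading vectors, using the training score normalization so that
        projecting the training data reproduces the fit.
        """
        X = np.asarray(X, dtype=float)
        Xr = self.center_.apply(X)
        out = np.empty((X.shape[0], self.n_components_))
        for i in range(self.n_components_):
            out[:, i] = Xr @ directions[:, i]
            t_new = (Xr @ self._deflation_dirs[:, i]) / self.score_norms_[i]
            Xr = Xr - np.outer(t_new, self.deflation_loadings_[:, i])
        return out

    def transform(self, X) -> np.ndarray:
        """Score matrix: column i is the stage-i residual projected on B^(i)."""
        check_is_fitted(self, "coefs_")
        return self._staged_scores(X, self.coefs_)

    def to_dict(self) -> dict:
        check_is_fitted(self, "coefs_")
        return {
            "kind": "lda_pls",
            "n_components": self.n_components_,
            "n_lv": self.n_lv,
            "deflation": self.deflation,
            "mean": self.center_.column_means.tolist(),
            "directions_lda": self.directions_lda_.tolist(),
            "coefs": self.coefs_.tolist(),
            "deflation_loadings": self.deflation_loadings_.tolist(),
            "score_norms": self.score_norms_.tolist(),
        }


def fit_lda_pls(X, y, n_lv: int, n_components: int = 1, **kwargs) -> LDAPLS:
    """Functional wrapper over :class:`LDAPLS`."""
    return LDAPLS(n_components=n_components, n_lv=n_lv, **kwargs).fit(X, y)


def project(model: LDAPLS, X_new) -> np.ndarray:
    """Score matrix of new samples under a fitted LDA-PLS model."""
    return model.transform(X_new)


@dataclass
class LambdaSearchResult:
    """Outcome of the λ traversal on a held-out half of the training set."""

    best_lambda: float
    grid: np.ndarray
    val_accuracy: np.ndarray
    split_info: dict = field(default_factory=dict)


def _lambda_grid(step: float) -> np.ndarray:
    n_steps = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n_steps + 1)


def _grid_accuracies(
    S_sel: np.ndarray,
    y_sel: np.ndarray,
    S_ver: np.ndarray,
    y_ver: np.ndarray,
) -> np.ndarray:
    """Verification accuracy of the 1-D pooled-variance Gaussian rule,
    vectorized over the columns (one column per λ).

    Matches :class:`GaussianLinearClassifier` with d=1 exactly.
    """
    neg = y_sel == -1
    pos = y_sel == 1
    n1, n2 = int(neg.sum()), int(pos.sum())
    mu1 = S_sel[neg].mean(axis=0)
    mu2 = S_sel[pos].mean(axis=0)
    var = (
        ((S_sel[neg] - mu1) ** 2).sum(axis=0)
        + ((S_sel[pos] - mu2) ** 2).sum(axis=0)
    ) / (n1 + n2 - 2)
    var = np.maximum(var, 1e-300)
    coef = (mu2 - mu1) / var
    intercept = -0.5 * (mu2 + mu1) * coef + np.log(n2 / n1)
    dec = S_ver * coef + intercept
    pred = np.where(dec > 0, 1, -1)
    return (pred == y_ver[:, None]).mean(axis=0)


def search_lambda(
    X,
    y=None,
    n_lv: int = 1,
    step: float = LAMBDA_STEP,
    seed: int = 0,
    rtol: float = SVD_RTOL,
) -> LambdaSearchResult:
    """Traverse λ over ``{0, step, ..., 1}`` once, on a 50/50 split.

    The training set is split into a selection half (fits LDA and LDA-PLS
    and the per-λ classifier) and a verification half (scores each blended
    direction); the smallest λ attaining the maximum verification accuracy
    wins.
    """
    from .dataset import LabeledDataset

    if isinstance(X, LabeledDataset):
        X, y = X.X, X.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    idx = np.arange(len(y))
    idx_sel, idx_ver = train_test_split(
        idx, train_size=0.5, stratify=y, random_state=int(seed) % (2**31)
    )
    y_sel, y_ver = y[idx_sel], y[idx_ver]
    for part, name in ((y_sel, "selection"), (y_ver, "verification")):
        for label in (-1, 1):
            if (part == label).sum() < 2:
                raise ValueError(
                    f"lambda search split left < 2 samples of class {label} "
                    f"in the {name} half; use a larger dataset or another seed"
                )
    model = LDAPLS(n_components=1, n_lv=n_lv, rtol=rtol).fit(X[idx_sel], y_sel)
    w_hat = _unit(model.directions_lda_[:, 0], "w_lda")
    b_hat = _unit(model.coefs_[:, 0], "B_ldapls")

    grid = _lambda_grid(step)
    Xc_sel = model.center_.apply(X[idx_sel])
    Xc_ver = model.center_.apply(X[idx_ver])
    # scores along each blended direction; the normalization of w(λ) only
    # rescales the 1-D scores and cannot change the Gaussian rule's labels
    mix = (1.0 - grid)[None, :] * w_hat[:, None] + grid[None, :] * b_hat[:, None]
    acc = _grid_accuracies(Xc_sel @ mix, y_sel, Xc_ver @ mix, y_ver)
    best = int(np.argmax(acc))  # first max -> smallest λ on ties
    return LambdaSearchResult(
        best_lambda=float(grid[best]),
        grid=grid,
        val_accuracy=acc,
        split_info={"selection": idx_sel.tolist(), "verification": idx_ver.tolist()},
    )


class ExLDAPLS(TransformerMixin, BaseEstimator):
    """ex-LDA-PLS: λ-blended projection between LDA and LDA-PLS.

    With ``lam=None`` (default) λ is estimated by :func:`search_lambda` on
    the training data; a float fixes it.  The model then refits LDA-PLS on
    the full training set and blends each component's LDA direction with
    its coefficient vector at the chosen λ.
    """

    def __init__(
        self,
        n_components: int = 1,
        n_lv: int = 1,
        lam: float | None = None,
        lambda_step: float = LAMBDA_STEP,
        random_state: int = 0,
        rtol: float = SVD_RTOL,
    ):
        self.n_components = n_components
        self.n_lv = n_lv
        self.lam = lam
        self.lambda_step = lambda_step
        self.random_state = random_state
        self.rtol = rtol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.lam is None:
            self.search_result_ = search_lambda(
                X,
                y,
                n_lv=self.n_lv,
                step=self.lambda_step,
                seed=self.random_state,
                rtol=self.rtol,
            )
            self.lambda_ = self.search_result_.best_lambda
        else:
            self.search_result_ = None
            self.lambda_ = float(self.lam)
        self.base_model_ = LDAPLS(
            n_components=self.n_components, n_lv=self.n_lv, rtol=self.rtol
        ).fit(X, y)
        self.directions_ = np.column_stack(
            [
                combine_ex(
                    self.base_model_.directions_lda_[:, i],
                    self.base_model_.coefs_[:, i],
                    self.lambda_,
                ).w_combined
                for i in range(self.base_model_.n_components_)
            ]
        )
        self.n_components_ = self.base_model_.n_components_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Stage residuals projected onto the blended directions."""
        check_is_fitted(self, "directions_")
        return self.base_model_._staged_scores(X, self.directions_)

    def to_dict(self) -> dict:
        check_is_fitted(self, "directions_")
        d = self.base_model_.to_dict()
        d.update(
            kind="ex_lda_pls",
            lam=self.lambda_,
            directions=self.directions_.tolist(),
        )
        return d
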