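"""Comparative-evaluation harness for the dimension-reduction pipelines.

The protocol mirrors standard chemometric practice for method comparison:
stratified 7:3 train/test splits repeated 20 times; on each training part
the latent-variable count is chosen by stratified 10-fold cross-validation
over 1..10 (and λ by the held-out traversal for ex-LDA-PLS); the reduced
scores feed one shared linear Gaussian classifier; accuracy, G-Mean and
F-Value are reported per run and averaged.

Baselines: PCA keeping the smallest component count whose cumulative
explained-variance fraction reaches a threshold (default 0.95), plain
LDA, plain PLS scores, and PLS-LDA (LDA on the PLS score matrix).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classify import GaussianLinearClassifier, confusion_metrics
from .dataset import LabeledDataset
from .lda import LinearDiscriminantDirection, lda_direction
from .lda_pls import LDAPLS, ExLDAPLS
from .pls import NipalsPLS

logger = logging.getLogger(__name__)

METHODS = ("pca", "lda", "pls", "pls_lda", "lda_pls", "ex_lda_pls")
LV_METHODS = ("pls", "pls_lda", "lda_pls", "ex_lda_pls")


def _as_xy(data, y=None):
    if isinstance(data, LabeledDataset):
        return data.X, data.y
    return np.asarray(data, dtype=float), np.asarray(y)


def _derive_seed(seed: int, *parts: int) -> int:
    """Deterministic sub-seed below 2**31."""
    out = int(seed) % (2**31)
    for p in parts:
        out = (out * 1_000_003 + int(p) + 1) % (2**31 - 1)
    return out


def pca_baseline(train_X, rate: float = 0.95):
    """PCA components reaching the cumulative contribution rate.

    Returns ``(components, d)`` where ``components`` is ``k x d``
    orthonormal and ``d`` the smallest count whose cumulative
    explained-variance fraction is >= ``rate``.
    """
    train_X = np.asarray(train_X, dtype=float)
    if not 0 < rate <= 1:
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    pca = PCA(svd_solver="full").fit(train_X)
    ratios = pca.explained_variance_ratio_
    if not np.any(ratios > 0):
        raise ValueError("zero total variance: PCA baseline undefined")
    cum = np.cumsum(ratios)
    d = int(np.searchsorted(cum, rate - 1e-12) + 1)
    d = min(d, len(ratios))
    return pca.components_[:d].T, d


class PCAReducer(TransformerMixin, BaseEstimator):
    """PCA projection keeping either a fixed count or a contribution rate."""

    def __init__(self, n_components: int | None = None, rate: float = 0.95):
        self.n_components = n_components
        self.rate = rate

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        if self.n_components is None:
            self.components_, self.n_components_ = pca_baseline(X, self.rate)
        else:
            d = int(self.n_components)
            pca = PCA(n_components=d, svd_solver="full").fit(X)
            self.components_ = pca.components_.T
            self.n_components_ = d
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_


class PLSReducer(TransformerMixin, BaseEstimator):
    """Plain PLS: the latent score matrix T as reduced features."""

    def __init__(self, n_lv: int = 1):
        self.n_lv = n_lv

    def fit(self, X, y):
        n_lv = min(self.n_lv, len(y) - 1, X.shape[1])
        self.pls_ = NipalsPLS(n_components=n_lv).fit(X, np.asarray(y, dtype=float))
        return self

    def transform(self, X):
        return self.pls_.transform(X)


class PLSLDAReducer(TransformerMixin, BaseEstimator):
    """PLS-LDA: PLS score reduction followed by LDA on the scores.

    The pipeline yields one-dimensional projections (a single discriminant
    direction exists for two classes).
    """

    def __init__(self, n_lv: int = 1):
        self.n_lv = n_lv

    def fit(self, X, y):
        n_lv = min(self.n_lv, len(y) - 1, X.shape[1])
        self.pls_ = NipalsPLS(n_components=n_lv).fit(X, np.asarray(y, dtype=float))
        T = self.pls_.x_scores_
        self.direction_ = lda_direction(T, np.asarray(y))
        self.t_mean_ = T.mean(axis=0)
        return self

    def transform(self, X):
        T = self.pls_.transform(X)
        return (T - self.t_mean_) @ self.direction_[:, None]


def pls_lda_baseline(X, y=None, n_lv: int = 1) -> PLSLDAReducer:
    """Functional wrapper over :class:`PLSLDAReducer`."""
    X, y = _as_xy(X, y)
    return PLSLDAReducer(n_lv=n_lv).fit(X, y)


def make_reducer(
    method: str,
    n_lv: int = 1,
    n_components: int = 1,
    pca_rate: float | None = 0.95,
    pca_components: int | None = None,
    lam: float | None = None,
    lambda_step: float = 1e-3,
    random_state: int = 0,
):
    """Instantiate the reduction pipeline for one protocol method."""
    if method == "pca":
        return PCAReducer(n_components=pca_components, rate=pca_rate or 0.95)
    if method == "lda":
        return LinearDiscriminantDirection()
    if method == "pls":
        return PLSReducer(n_lv=n_lv)
    if method == "pls_lda":
        return PLSLDAReducer(n_lv=n_lv)
    if method == "lda_pls":
        return LDAPLS(n_components=n_components, n_lv=n_lv)
    if method == "ex_lda_pls":
        return ExLDAPLS(
            n_components=n_components,
            n_lv=n_lv,
            lam=lam,
            lambda_step=lambda_step,
            random_state=random_state,
        )
    raise ValueError(f"unknown method {method!r}")


def cv_select_lv(
    X,
    y=None,
    method: str = "pls",
    lv_range=range(1, 11),
    n_folds: int = 10,
    seed: int = 0,
    n_components: int = 1,
    naive: bool = False,
) -> int:
    """Latent-variable count by stratified k-fold cross-validation.

    Mean validation accuracy per candidate; smallest LV wins ties.
    """
    X, y = _as_xy(X, y)
    if method not in LV_METHODS:
        raise ValueError(f"method {method!r} has no latent-variable parameter")
    lv_range = sorted(int(v) for v in lv_range)
    counts = [int((y == c).sum()) for c in (-1, 1)]
    if min(counts) < n_folds:
        raise ValueError(
            f"infeasible folds: smallest class has {min(counts)} samples "
            f"< {n_folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=_derive_seed(seed))
    folds = list(skf.split(X, y))
    mean_acc = []
    for lv in lv_range:
        accs = []
        for f, (tr, va) in enumerate(folds):
            reducer = make_reducer(
                method,
                n_lv=lv,
                n_components=n_components,
                random_state=_derive_seed(seed, lv, f),
            )
            reducer.fit(X[tr], y[tr])
            clf = GaussianLinearClassifier(naive=naive).fit(
                reducer.transform(X[tr]), y[tr]
            )
            pred = clf.predict(reducer.transform(X[va]))
            accs.append((pred == y[va]).mean())
        mean_acc.append(float(np.mean(accs)))
    return lv_range[int(np.argmax(mean_acc))]


@dataclass
class EvalReport:
    """Per-method, per-run metric records plus their means.

    ``records`` has one row per (method, run) with train/test accuracy,
    G-Mean and F-Value; ``means`` aggregates per method (NaN-flagged
    degenerate metrics are excluded and counted in ``failures``).
    """

    records: pd.DataFrame
    config: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    @property
    def means(self) -> pd.DataFrame:
        cols = ["train_acc", "test_acc", "gmean", "fvalue"]
        return self.records.groupby("method", sort=False)[cols].mean()

    def to_csv(self) -> str:
        buf = _io.StringIO()
        self.records.to_csv(buf, index=False, float_format="%.10g")
        buf.write("\n# means\n")
        self.means.to_csv(buf, float_format="%.10g")
        return buf.getvalue()

    def table(self) -> str:
        """Pretty table, one method per row: Train Acc, Test Acc, G-Mean, F-Value."""
        m = self.means.rename(
            columns={
                "train_acc": "Train Acc",
                "test_acc": "Test Acc",
                "gmean": "G-Mean",
                "fvalue": "F-Value",
            }
        )
        return m.to_string(float_format=lambda v: f"{v:.4f}")


def _evaluate_method(
    method, Xtr, ytr, Xte, yte, *, lv_range, pca_rate, pca_components,
    n_components, lambda_step, cv_folds, select_lv, n_lv, naive, run_seed,
):
    chosen_lv = n_lv
    if method in LV_METHODS and select_lv:
        chosen_lv = cv_select_lv(
            Xtr,
            ytr,
            method=method,
            lv_range=lv_range,
            n_folds=cv_folds,
            seed=run_seed,
            n_components=n_components,
            naive=naive,
        )
    reducer = make_reducer(
        method,
        n_lv=chosen_lv,
        n_components=n_components,
        pca_rate=pca_rate,
        pca_components=pca_components,
        lambda_step=lambda_step,
        random_state=_derive_seed(run_seed, 7),
    )
    reducer.fit(Xtr, ytr)
    Str, Ste = reducer.transform(Xtr), reducer.transform(Xte)
    clf = GaussianLinearClassifier(naive=naive).fit(Str, ytr)
    m_tr = confusion_metrics(ytr, clf.predict(Str))
    m_te = confusion_metrics(yte, clf.predict(Ste))
    return {
        "train_acc": m_tr["acc"],
        "test_acc": m_te["acc"],
        "gmean": m_te["gmean"],
        "fvalue": m_te["fvalue"],
        "n_lv": chosen_lv if method in LV_METHODS else np.nan,
        "lambda": getattr(reducer, "lambda_", np.nan),
        "degenerate": m_te["degenerate"],
    }


def repeated_split_eval(
    X,
    y=None,
    methods=METHODS,
    split_ratio: float = 0.7,
    n_runs: int = 20,
    seed: int = 0,
    lv_range=range(1, 11),
    pca_rate: float | None = 0.95,
    pca_components: int | None = None,
    n_components: int = 1,
    lambda_step: float = 1e-3,
    cv_folds: int = 10,
    select_lv: bool = True,
    n_lv: int = 1,
    naive: bool = False,
) -> EvalReport:
    """Repeated stratified train/test comparison of the pipelines.

    Each run draws a stratified ``split_ratio`` train part, selects
    hyperparameters strictly inside it, fits, and scores both parts with
    the shared Gaussian linear classifier.  The report carries per-run
    records and per-method means; a method failing on a run is excluded
    for that run and counted.
    """
    X, y = _as_xy(X, y)
    rows = []
    failures = {m: 0 for m in methods}
    for r in range(n_runs):
        run_seed = _derive_seed(seed, r)
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, train_size=split_ratio, stratify=y, random_state=run_seed
        )
        for method in methods:
            try:
                rec = _evaluate_method(
                    method,
                    X[tr],
                    y[tr],
                    X[te],
                    y[te],
                    lv_range=lv_range,
                    pca_rate=pca_rate,
                    pca_components=pca_components,
                    n_components=n_components,
                    lambda_step=lambda_step,
                    cv_folds=cv_folds,
                    select_lv=select_lv,
                    n_lv=n_lv,
                    naive=naive,
                    run_seed=run_seed,
                )
            except Exception as exc:  # noqa: BLE001 - per-run robustness
                failures[method] += 1
                logger.warning("method %s failed on run %d: %s", method, r, exc)
                continue
            rec.update(method=method, run=r)
            rows.append(rec)
    records = pd.DataFrame(
        rows,
        columns=[
            "method", "run", "train_acc", "test_acc",
            "gmean", "fvalue", "n_lv", "lambda", "degenerate",
        ],
    )
    config = {
        "methods": list(methods),
        "split_ratio": split_ratio,
        "n_runs": n_runs,
        "seed": int(seed),
        "lv_range": [int(v) for v in lv_range],
        "pca_rate": pca_rate,
        "pca_components": pca_components,
        "n_components": n_components,
        "lambda_step": lambda_step,
        "cv_folds": cv_folds,
        "select_lv": select_lv,
        "n_lv": n_lv,
        "naive": naive,
    }
    return EvalReport(records=records, config=config, failures=failures)


def components_sweep(
    X,
    y=None,
    methods=("pca", "lda_pls", "ex_lda_pls"),
    component_range=range(1, 31),
    n_lv: int = 1,
    split_ratio: float = 0.7,
    n_runs: int = 20,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Mean accuracies versus the number of extracted components.

    For each count the repeated-split protocol is run with that many PCA
    components or LDA-PLS/ex-LDA-PLS outer components (latent variables
    fixed at ``n_lv``); returns a long-format curve table.
    """
    X, y = _as_xy(X, y)
    rows = []
    for comp in component_range:
        comp = int(comp)
        report = repeated_split_eval(
            X,
            y,
            methods=methods,
            split_ratio=split_ratio,
            n_runs=n_runs,
            seed=seed,
            pca_components=comp,
            n_components=comp,
            select_lv=False,
            n_lv=n_lv,
            **kwargs,
        )
        for method, mean in report.means.iterrows():
            rows.append(
                {
                    "method": method,
                    "n_components": comp,
                    "train_acc": mean["train_acc"],
                    "test_acc": mean["test_acc"],
                }
            )
    return pd.DataFrame(rows)
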