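"""Labeled two-class datasets: container, delimited-file I/O, centering.

All downstream algorithms (LDA, NIPALS-PLS, LDA-PLS) operate on a plain
``n x k`` feature matrix with a two-valued label vector.  Internally labels
are always coded -1/+1; the class coded +1 is the "positive" class for
G-Mean / F-Value.  Textual or arbitrary numeric labels are mapped onto
(-1, +1) by sorted order, which makes the coding deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_KNOWN_DELIMITERS = (",", "\t", ";")


class DegenerateLabelsError(ValueError):
    """Fewer than two classes, or an empty class, where two are required."""


class EmptyDatasetError(ValueError):
    """No rows survived loading/cleaning."""


@dataclass
class LabeledDataset:
    """An ``n x k`` feature matrix with a -1/+1 label vector.

    Parameters
    ----------
    X : ndarray of shape (n, k)
        Feature matrix, samples in rows.  Must be finite.
    y : ndarray of shape (n,)
        Labels coded -1/+1.
    feature_ids : list of str, optional
        Column identifiers (e.g. wavenumbers for spectra).
    label_values : tuple
        The original label pair ``(negative_label, positive_label)`` that
        was mapped onto (-1, +1).
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str] | None = None
    label_values: tuple = (-1, 1)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (samples x features)")
        n, k = self.X.shape
        if n < 1 or k < 1:
            raise EmptyDatasetError("empty dataset: need n, k >= 1")
        if self.y.shape != (n,):
            raise ValueError(f"y has length {self.y.shape}, expected ({n},)")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        values = np.unique(self.y)
        if values.size != 2:
            raise DegenerateLabelsError(
                f"degenerate labels: need exactly 2 classes, got {values.size}"
            )
        if not set(values) <= {-1, 1}:
            raise ValueError("internal labels must be coded -1/+1")
        for v in values:
            if int((self.y == v).sum()) < 2:
                raise DegenerateLabelsError(
                    f"degenerate labels: class {v} has < 2 samples"
                )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_split(self) -> tuple[np.ndarray, np.ndarray]:
        """Rows of the -1 class and of the +1 class, in that order."""
        return self.X[self.y == -1], self.X[self.y == 1]


def map_labels(raw: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Map a two-valued label vector onto -1/+1 by sorted order.

    The smaller value (lexicographic for strings, numeric otherwise)
    becomes -1, the larger +1.  Returns the coded vector and the original
    ``(negative_label, positive_label)`` pair.
    """
    values = sorted(pd.unique(raw).tolist())
    if len(values) != 2:
        raise DegenerateLabelsError(
            f"degenerate labels: need exactly 2 classes, got {len(values)}"
        )
    neg, pos = values
    coded = np.where(np.asarray(raw) == pos, 1, -1)
    return coded, (neg, pos)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="".join(_KNOWN_DELIMITERS)).delimiter
    except csv.Error:
        return ","


def load_labeled_delimited(
    path_X: str | Path,
    path_or_column_y: str | Path | int = -1,
    delimiter: str | None = None,
    header: bool = False,
) -> LabeledDataset:
    """Load a labeled dataset from delimited text.

    Parameters
    ----------
    path_X : path
        Delimited file with samples in rows, features in columns.
    path_or_column_y : path or int
        Either a separate one-column label file, or the (0-based, negative
        allowed) index of the label column inside ``path_X``.
    delimiter : str, optional
        Explicit delimiter; auto-detected among ``, \\t ;`` when omitted.
    header : bool
        Whether the first row holds column names.

    Rows with any non-numeric or missing feature cell are dropped (and
    counted in the log).  Labels are mapped to -1/+1 by sorted order.
    """
    path_X = Path(path_X)
    if delimiter is None:
        delimiter = _sniff_delimiter(path_X)
    frame = pd.read_csv(path_X, sep=delimiter, header=0 if header else None)

    if isinstance(path_or_column_y, int):
        label_col = frame.columns[path_or_column_y]
        raw_labels = frame[label_col].to_numpy()
        features = frame.drop(columns=[label_col])
    else:
        lab = pd.read_csv(path_or_column_y, sep=delimiter, header=0 if header else None)
        if lab.shape[1] != 1:
            raise ValueError("label file must have exactly one column")
        raw_labels = lab.iloc[:, 0].to_numpy()
        features = frame
        if len(raw_labels) != len(features):
            raise ValueError("label file length does not match feature file")

    numeric = features.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with non-numeric/missing features", n_dropped)
    X = numeric.to_numpy(dtype=float)[keep]
    raw_labels = raw_labels[keep]
    if X.shape[0] == 0:
        raise EmptyDatasetError("empty dataset: no rows survived cleaning")
    y, label_values = map_labels(raw_labels)
    feature_ids = [str(c) for c in features.columns] if header else None
    return LabeledDataset(X=X, y=y, feature_ids=feature_ids, label_values=label_values)


def write_labeled_delimited(
    dataset: LabeledDataset, path: str | Path, delimiter: str = ",",
) -> None:
    """Write features plus a final label column as delimited text."""
    frame = pd.DataFrame(dataset.X)
    frame["label"] = dataset.y
    frame.to_csv(path, sep=delimiter, header=False, index=False)


@dataclass
class CenteringTransform:
    """Column centering learned on training data, applied to any matrix.

    Optionally also scales columns to unit variance (off by default: the
    algorithms here only presume centering).
    """

    column_means: np.ndarray
    column_scales: np.ndarray | None = None
    applied: bool = field(default=False, compare=False)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.column_means.shape[0]:
            raise ValueError(
                f"dimension mismatch: got {X.shape[-1]} columns, "
                f"transform expects {self.column_means.shape[0]}"
            )
        out = X - self.column_means
        if self.column_scales is not None:
            out = out / self.column_scales
        self.applied = True
        return out

    def revert(self, Xc: np.ndarray) -> np.ndarray:
        out = np.asarray(Xc, dtype=float)
        if self.column_scales is not None:
            out = out * self.column_scales
        return out + self.column_means


def fit_center(X: np.ndarray | LabeledDataset, scale: bool = False) -> CenteringTransform:
    """Learn per-column means (and optionally unit-variance scales)."""
    if isinstance(X, LabeledDataset):
        X = X.X
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    scales = None
    if scale:
        scales = X.std(axis=0, ddof=1)
        scales = np.where(scales > 0, scales, 1.0)
    return CenteringTransform(column_means=means, column_scales=scales)


def apply_center(transform: CenteringTransform, X: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`CenteringTransform.apply`."""
    return transform.apply(X)
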