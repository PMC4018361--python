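"""Seeded generators for the two study geometries.

``make_toy2d`` reconstructs the two-dimensional illustration geometry:
two linearly separable classes whose bulk forms wide horizontal bands,
plus a fraction of "horizontal" outliers displaced far along x and
diagonally away from the class band.  The outliers contribute a strong
cross-covariance to the pooled within-class scatter, which tilts the
plain-LDA direction off the ideal (vertical) separator; the mean
difference — and hence the one-LV LDA-PLS coefficient vector, which is
proportional to it — tilts the *other* way, so the λ-blend family sweeps
through the ideal direction.

``make_collinear_spectra`` emulates spectra-like data: a few informative
smooth basis functions (Gaussian bands of width ``collinearity_length``)
carry the class signal across neighboring features, giving the extensive
neighbor collinearity typical of vibrational spectra; with
``small_sample_flag`` the feature count exceeds the sample count and the
within-class scatter is singular, exercising the SVD pseudo-inverse path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset


@dataclass
class ToyConfig:
    """Frozen default geometry of the two-dimensional toy set.

    ``n`` samples split evenly between labels -1/+1.  Bulk points lie in
    horizontal bands ``y = ±class_gap/2 ± band_halfwidth`` with x spread
    uniformly over ``±x_spread``; an ``outlier_fraction`` of each class
    sits at ``|x|`` up to ``outlier_shift`` and is lifted diagonally away
    from the boundary by up to ``outlier_rise``.  Classes stay separable
    along the vertical with margin ``class_gap - 2*band_halfwidth``.
    """

    n: int = 1224
    class_gap: float = 2.0
    band_halfwidth: float = 0.3
    x_spread: float = 6.0
    outlier_fraction: float = 0.18
    outlier_shift: float = 12.0
    outlier_rise: float = 5.0
    margin_epsilon: float = 1e-6
    seed: int = 2013

    def validate(self) -> None:
        if self.n < 8:
            raise ValueError("n must be >= 8")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.class_gap <= 2 * self.band_halfwidth:
            raise ValueError(
                "class_gap must exceed 2*band_halfwidth for separability"
            )


@dataclass
class SpectraConfig:
    """High-dimensional collinear "spectra" generator settings.

    ``n_informative`` Gaussian bands of width ``collinearity_length``
    (feature-index units) carry a latent class signal of size
    ``class_shift`` (class-mean separation per latent, in units of the
    unit within-class latent spread); ``noise_sd`` is iid per-feature
    noise.  ``small_sample_flag`` asserts k > n.
    """

    n: int = 200
    k: int = 500
    n_informative: int = 4
    collinearity_length: float = 25.0
    class_shift: float = 4.0
    noise_sd: float = 0.1
    small_sample_flag: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_informative <= self.k:
            raise ValueError("need k >= n_informative >= 1")
        if self.n < 8:
            raise ValueError("n must be >= 8")
        if self.small_sample_flag and self.k <= self.n:
            raise ValueError("small_sample_flag requires k > n")
        if self.collinearity_length <= 0 or self.noise_sd < 0:
            raise ValueError("invalid smoothing/noise settings")


def make_toy2d(config: ToyConfig | None = None, **overrides) -> LabeledDataset:
    """Generate the two-dimensional toy dataset (pure function of config+seed)."""
    if config is None:
        config = ToyConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    half = config.n // 2
    n_out = int(round(config.outlier_fraction * half))
    n_bulk = half - n_out
    rows, labels = [], []
    for s in (-1, 1):
        band_center = s * config.class_gap / 2.0
        bx = rng.uniform(-config.x_spread, config.x_spread, size=n_bulk)
        by = band_center + rng.uniform(
            -config.band_halfwidth, config.band_halfwidth, size=n_bulk
        )
        ox = s * rng.uniform(0.5, 1.0, size=n_out) * config.outlier_shift
        oy = band_center + s * rng.uniform(0.5, 1.0, size=n_out) * config.outlier_rise
        rows.append(np.column_stack([np.r_[bx, ox], np.r_[by, oy]]))
        labels.append(np.full(half, s))
    X = np.vstack(rows)
    y = np.concatenate(labels)
    # separability audit along the vertical axis
    margin = X[y == 1, 1].min() - X[y == -1, 1].max()
    if margin < config.margin_epsilon:
        raise ValueError(
            f"config violates separability: vertical margin {margin:.3g} "
            f"< {config.margin_epsilon}"
        )
    perm = rng.permutation(len(y))
    return LabeledDataset(X=X[perm], y=y[perm], feature_ids=["x", "y"])


def _smooth_basis(k: int, n_informative: int, width: float) -> np.ndarray:
    """Unit-norm Gaussian bands evenly spread over the feature axis."""
    centers = (np.arange(n_informative) + 0.5) * k / n_informative
    idx = np.arange(k)
    G = np.exp(-0.5 * ((idx[None, :] - centers[:, None]) / width) ** 2)
    return G / np.linalg.norm(G, axis=1, keepdims=True)


def make_collinear_spectra(
    config: SpectraConfig | None = None, **overrides
) -> LabeledDataset:
    """Generate collinear spectra-like data (pure function of config+seed)."""
    if config is None:
        config = SpectraConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    half = config.n // 2
    n = 2 * half
    y = np.r_[np.full(half, -1), np.full(half, 1)]
    G = _smooth_basis(config.k, config.n_informative, config.collinearity_length)
    # latent class signal along a fixed random unit direction
    v = rng.standard_normal(config.n_informative)
    v /= np.linalg.norm(v)
    Z = (
        y[:, None] * (config.class_shift / 2.0) * v[None, :]
        + rng.standard_normal((n, config.n_informative))
    )
    X = Z @ G + config.noise_sd * rng.standard_normal((n, config.k))
    perm = rng.permutation(n)
    return LabeledDataset(X=X[perm], y=y[perm])
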