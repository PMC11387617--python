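"""Standardize-then-PCA preprocessing for high-dimensional teachers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["Projection", "reduce_dimensions"]


@dataclass(frozen=True)
class Projection:
    """Composition of feature standardization and orthonormal PCA loadings.

    ``transform(X) = ((X - center) / scale) @ loadings`` maps raw features
    to principal-component scores; ``compose_beta`` maps reduced-space
    coefficients back to the raw feature scale (plus the constant offset
    induced by centering) so linear prediction on raw features is
    well-defined.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (p, r), orthonormal columns
    explained_variance_ratio: np.ndarray

    @property
    def rank(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.center) / self.scale) @ self.loadings

    def compose_beta(self, beta_reduced):
        """Raw-scale coefficients and offset: X @ beta + offset == Z @ beta_reduced."""
        beta_reduced = np.asarray(beta_reduced, dtype=float)
        w = self.loadings @ beta_reduced
        beta = w / self.scale
        offset = -float((self.center / self.scale) @ w)
        return beta, offset

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Projection":
        return cls(
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(
                d["explained_variance_ratio"], dtype=float
            ),
        )


def reduce_dimensions(X, rank):
    """Principal-component scores of the standardized covariate matrix.

    Parameters
    ----------
    X : (n, p) array
    rank : int or float
        An integer keeps exactly ``rank`` components (must be
        <= min(n, p)); a fraction in (0, 1) keeps the smallest number of
        components whose cumulative explained variance reaches it.

    Returns
    -------
    (Projection, Z) where Z is the (n, r) score matrix.

    Zero-variance features are kept with their scale set to 1 (a warning is
    emitted); they contribute nothing to the scores.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s); scale set to 1",
            UserWarning,
            stacklevel=2,
        )
        scale = np.where(zero, 1.0, scale)
    Z0 = (X - center) / scale

    pca = PCA(svd_solver="full")
    Z_full = pca.fit_transform(Z0)
    evr = pca.explained_variance_ratio_
    if isinstance(rank, (int, np.integer)):
        if not 1 <= rank <= min(n, p):
            raise ValueError(f"rank must be in [1, min(n, p)] = [1, {min(n, p)}]")
        r = int(rank)
    else:
        rank = float(rank)
        if not 0 < rank < 1:
            raise ValueError("variance fraction must lie in (0, 1)")
        # smallest r with cumulative explained variance >= fraction
        r = int(np.searchsorted(np.cumsum(evr), rank - 1e-12) + 1)
        r = min(r, evr.shape[0])
    proj = Projection(
        center=center,
        scale=scale,
        loadings=pca.components_[:r].T,
        explained_variance_ratio=evr[:r],
    )
    return proj, Z_full[:, :r]
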