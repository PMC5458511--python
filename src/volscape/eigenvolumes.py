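"""Principal component analysis over aligned volume ensembles.

With N class volumes and millions of voxels, the covariance never fits in
memory but its N x N Gram matrix does: eigendecomposing the Gram matrix of the
masked, mean-centered, flattened volumes gives the same eigenvolumes as a
direct SVD of the data matrix. Each class is then summarised by K "linear
factors" — its inner products with the orthonormal eigenvolumes — which span
the low-dimensional conformational space the energy landscape is built over.

PCA here is unweighted: every class contributes equally regardless of its
particle count. Counts enter only later, when occupancies are turned into
free energies. A count-weighted variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .align import AlignedEnsemble
from .volume_io import BinaryMask, DegenerateInputError, VoxelGrid

__all__ = ["VolumePCA", "EigenDecomposition", "fit_pca", "project", "explained_variance"]


class VolumePCA(TransformerMixin, BaseEstimator):
    """PCA of flattened masked volumes via the Gram-matrix trick.

    Parameters
    ----------
    n_components
        Number K of eigenvolumes to retain; at most N - 1.
    count_weighted
        If True, classes are weighted by sqrt of their particle counts
        (documented alternative; default off).

    Attributes
    ----------
    mean_ : (n_masked,) masked mean volume.
    components_ : (K, n_masked) orthonormal eigenvolumes (masked, flattened).
    eigenvalues_ : (K,) descending sums of squared coefficients.
    explained_variance_ratio_ : (K,) eigenvalues_ / total centered variance.
    coefficients_ : (N, K) linear factors of the training classes.
    """

    def __init__(self, n_components: int = 2, count_weighted: bool = False):
        self.n_components = n_components
        self.count_weighted = count_weighted

    def fit(self, X, y=None, sample_counts=None):
        """Fit on an (N, n_masked) matrix of masked, flattened volumes."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_classes, n_masked_voxels)")
        n = X.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 classes, got {n}")
        if not 1 <= self.n_components <= n - 1:
            raise ValueError(f"n_components must be in [1, {n - 1}], got {self.n_components}")
        w = np.ones(n)
        if self.count_weighted:
            if sample_counts is None:
                raise ValueError("count_weighted=True requires sample_counts")
            w = np.sqrt(np.asarray(sample_counts, dtype=float))
            w = w / w.mean()
        self.mean_ = (w[:, None] ** 2 * X).sum(axis=0) / (w**2).sum()
        xc = (X - self.mean_) * w[:, None]
        gram = xc @ xc.T
        self.total_variance_ = float(np.trace(gram))
        if self.total_variance_ < 1e-20:
            raise DegenerateInputError("zero-variance ensemble: all volumes identical")
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1][: self.n_components]
        lam = np.clip(evals[order], 0.0, None)
        u = evecs[:, order]
        safe = np.sqrt(np.where(lam > 1e-30, lam, 1.0))
        comps = (xc.T @ u) / safe  # (n_masked, K), unit columns
        # sign convention: largest-magnitude voxel of each eigenvolume positive
        for k in range(comps.shape[1]):
            j = int(np.argmax(np.abs(comps[:, k])))
            if comps[j, k] < 0:
                comps[:, k] *= -1.0
                u[:, k] *= -1.0
        self.components_ = comps.T
        self.eigenvalues_ = lam
        self.explained_variance_ratio_ = lam / self.total_variance_
        self.coefficients_ = (X - self.mean_) @ self.components_.T
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Linear factors of (possibly new) masked, flattened volumes."""
        if not hasattr(self, "components_"):
            raise RuntimeError("VolumePCA is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-length mismatch with the fitted mask")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, coeffs) -> np.ndarray:
        coeffs = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
        return self.mean_ + coeffs @ self.components_


@dataclass
class EigenDecomposition:
    """Volume-shaped view of a fitted :class:`VolumePCA`."""

    mean_volume: VoxelGrid
    eigenvolumes: list[VoxelGrid]
    eigenvalues: np.ndarray
    coefficients: np.ndarray
    analysis_mask: BinaryMask
    total_variance: float
    estimator: VolumePCA

    @property
    def n_components(self) -> int:
        return len(self.eigenvolumes)


def _masked_matrix(ensemble: AlignedEnsemble, mask: BinaryMask) -> np.ndarray:
    stack = ensemble.stack()
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask shape does not match the ensemble volumes")
    return stack[:, mask.data]


def _unflatten(vec: np.ndarray, mask: BinaryMask, like: VoxelGrid) -> VoxelGrid:
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask.data] = vec
    return VoxelGrid(out, like.voxel_size, like.origin)


def fit_pca(
    ensemble: AlignedEnsemble,
    mask: BinaryMask,
    n_components: int,
    count_weighted: bool = False,
) -> EigenDecomposition:
    """Eigenvolume decomposition of an aligned ensemble inside ``mask``."""
    X = _masked_matrix(ensemble, mask)
    est = VolumePCA(n_components=n_components, count_weighted=count_weighted)
    est.fit(X, sample_counts=ensemble.counts if count_weighted else None)
    like = ensemble.volumes[0]
    return EigenDecomposition(
        mean_volume=_unflatten(est.mean_, mask, like),
        eigenvolumes=[_unflatten(c, mask, like) for c in est.components_],
        eigenvalues=est.eigenvalues_,
        coefficients=est.coefficients_,
        analysis_mask=mask,
        total_variance=est.total_variance_,
        estimator=est,
    )


def project(volume: VoxelGrid, decomposition: EigenDecomposition) -> np.ndarray:
    """Linear factors of one volume towards the eigenvolumes."""
    if volume.shape != decomposition.analysis_mask.shape:
        raise ValueError("volume is not on the decomposition's grid")
    vec = volume.data.astype(np.float64)[decomposition.analysis_mask.data]
    return decomposition.estimator.transform(vec)[0]


def explained_variance(decomposition: EigenDecomposition) -> np.ndarray:
    """Fraction of the total centered variance captured per component."""
    return decomposition.eigenvalues / decomposition.total_variance
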