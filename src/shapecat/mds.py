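"""Classical (Torgerson) multidimensional scaling of RDMs.

Double-centres the squared dissimilarities, eigendecomposes, and takes the
top-d eigenvectors scaled by the square root of their eigenvalues. Chosen
over stress-majorisation because it is deterministic and is the variant
typically behind RSA geometry figures. Non-Euclidean inputs produce negative
eigenvalues, which are truncated to zero with a warning; their mass is
reported as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ValidationError
from .rdm import RDM


@dataclass(frozen=True)
class Embedding:
    """A d-dimensional configuration recovered from an RDM."""

    conditions: tuple[str, ...]
    coordinates: np.ndarray      # (N, d), columns ordered by eigenvalue
    eigenvalues: np.ndarray      # d retained values, descending
    stress: float                # strain: spectral residual of the Gram fit
    negative_eigenvalue_mass: float  # Σ|λ<0| / Σ|λ|, non-Euclidean diagnostic


class ClassicalMDS(BaseEstimator):
    """Sklearn-style estimator for classical metric MDS on dissimilarities.

    Parameters
    ----------
    n_components : int
        Output dimensionality d (must satisfy d ≤ N − 1).

    Attributes
    ----------
    embedding_ : (N, d) coordinates
    eigenvalues_ : d retained eigenvalues, sorted descending
    stress_ : strain-type residual — the Frobenius misfit of the rank-d
        Gram-matrix approximation relative to the full spectrum, in [0, 1];
        non-increasing in ``n_components``
    negative_eigenvalue_mass_ : fraction of spectral mass below zero
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        d = self.n_components
        if d < 1:
            raise ValidationError("n_components must be ≥ 1")
        if D.shape != (n, n):
            raise ValidationError(f"dissimilarity matrix must be square, got {D.shape}")
        if d > n - 1:
            raise ValidationError(
                f"n_components = {d} exceeds N − 1 = {n - 1}"
            )
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        B = (B + B.T) / 2
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        total = np.abs(eigval).sum()
        neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total) if total > 0 else 0.0
        top = eigval[:d]
        if np.any(top < 0):
            warnings.warn(
                "negative eigenvalues among retained dimensions truncated to "
                "zero (non-Euclidean dissimilarities)", stacklevel=2)
        top = np.clip(top, 0.0, None)
        self.embedding_ = eigvec[:, :d] * np.sqrt(top)
        self.eigenvalues_ = top
        self.negative_eigenvalue_mass_ = neg_mass
        sq_total = float((eigval ** 2).sum())
        if sq_total == 0.0:
            self.stress_ = 0.0
        else:
            resid = sq_total - float((top ** 2).sum())
            self.stress_ = float(np.sqrt(max(resid, 0.0) / sq_total))
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_


def classical_mds(rdm: RDM, d: int = 2) -> Embedding:
    """Classical MDS embedding of an RDM into d dimensions."""
    est = ClassicalMDS(n_components=d).fit(rdm.values)
    return Embedding(
        conditions=rdm.conditions,
        coordinates=est.embedding_,
        eigenvalues=est.eigenvalues_,
        stress=est.stress_,
        negative_eigenvalue_mass=est.negative_eigenvalue_mass_,
    )
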