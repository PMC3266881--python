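"""PCA on the coancestry matrix, plus an Eigenstrat reference path.

The unlinked coancestry matrix is (up to an affine rescaling) the
individual-by-individual covariance matrix used by Eigenstrat, so its
leading eigenvectors reproduce classical genotype PCA; with a linked matrix
the same eigenanalysis additionally exploits LD and separates closer
populations.  The Eigenstrat implementation here is the comparison oracle,
not the primary analysis path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PcaResult", "normalize_coancestry", "pca", "eigenstrat_reference"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # (N, n_components), orthonormal columns
    normalization: str = "coancestry"

    def __post_init__(self) -> None:
        order = np.argsort(self.eigenvalues)[::-1]
        self.eigenvalues = np.asarray(self.eigenvalues)[order]
        self.components = np.asarray(self.components)[:, order]
        # sign convention: largest-magnitude loading positive
        for j in range(self.components.shape[1]):
            v = self.components[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                self.components[:, j] = -v


def normalize_coancestry(X: np.ndarray) -> np.ndarray:
    """Symmetrize and double-center a coancestry matrix.

    The linked matrix is slightly asymmetric (donor and recipient roles
    differ), so the average of ``X`` and its transpose is taken before
    removing row and column means; the result has zero row and column sums
    and a real spectrum.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("coancestry matrix must be square")
    S = (X + X.T) / 2.0
    row = S.mean(axis=1, keepdims=True)
    col = S.mean(axis=0, keepdims=True)
    return S - row - col + S.mean()


def _top_eigs(S: np.ndarray, n_components: int) -> tuple:
    """Descending eigenpairs; the trivial constant direction of a centered
    matrix is excluded.

    A doubly-centered matrix annihilates the all-ones vector, and because
    self-copying is excluded the remaining bulk spectrum is shifted
    uniformly downward — a shift that preserves the order of the meaningful
    eigenvectors but can park the exact-zero trivial eigenvalue in the
    middle of it.  Dropping that direction restores the structure ordering
    (and caps the reported components at N - 1).
    """
    N = S.shape[0]
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    scale = np.abs(S).max() + 1e-300
    if np.abs(S.sum(axis=1)).max() < 1e-8 * scale * N:
        ones = np.full(N, 1.0 / np.sqrt(N))
        trivial = int(np.argmax(np.abs(vecs.T @ ones)))
        keep = np.arange(N) != trivial
        vals, vecs = vals[keep], vecs[:, keep]
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pca(X_normalized: np.ndarray, n_components: int = 10) -> PcaResult:
    """Top eigenpairs of a symmetric (normalized) coancestry matrix."""
    S = np.asarray(X_normalized, dtype=float)
    N = S.shape[0]
    if n_components >= N:
        warnings.warn(f"n_components truncated to {N - 1}")
        n_components = N - 1
    vals, vecs = _top_eigs(S, n_components)
    return PcaResult(vals[:n_components], vecs[:, :n_components])


def eigenstrat_reference(genotypes: np.ndarray, n_components: int = 10,
                         ploidy: int = 2) -> PcaResult:
    """Classical genotype PCA with the Price et al. normalization.

    Each polymorphic site is mean-centered and divided by its binomial
    standard deviation ``sqrt(p (1 - p))`` with ``p`` the sample allele
    frequency; monomorphic sites are dropped.  The PCs are eigenvectors of
    the resulting individual-by-individual covariance matrix.
    """
    G = np.asarray(genotypes, dtype=float)
    N, L = G.shape
    p = G.mean(axis=0) / ploidy
    poly = (p > 0) & (p < 1)
    G = G[:, poly]
    p = p[poly]
    Z = (G - ploidy * p) / np.sqrt(p * (1.0 - p))
    C = Z @ Z.T / Z.shape[1]
    if n_components >= N:
        warnings.warn(f"n_components truncated to {N - 1}")
        n_components = N - 1
    vals, vecs = _top_eigs(C, n_components)
    return PcaResult(vals[:n_components], vecs[:, :n_components],
                     normalization="eigenstrat")
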