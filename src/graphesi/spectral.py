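"""Graph Laplacian spectral analysis of the source space.

The combinatorial Laplacian ``L = D - A`` of the source neighborhood graph
is symmetric positive semidefinite; its eigenvectors form an orthonormal
basis ordered by eigenvalue.  Projecting a vertex-indexed source pattern
onto this basis is the graph Fourier transform (GFT); eigenvectors of small
eigenvalue vary slowly across mesh edges, so keeping only the first ``k``
coefficients acts as a spatial low-pass filter that preserves extended
source patches while discarding spatially ragged components.

The notion of "frequency" on a graph is made concrete by counting sign
flips: the graph frequency of an eigenvector is the number of edges whose
endpoint values have strictly opposite signs — the graph analogue of zero
crossings of a sinusoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .source_space import SourceGraph

__all__ = [
    "Laplacian",
    "SpectralBasis",
    "laplacian",
    "eigendecompose",
    "gft",
    "igft",
    "graph_frequency",
    "select_low_band",
    "GraphLowBandTransform",
]


@dataclass
class Laplacian:
    """Combinatorial graph Laplacian ``L = D - A`` with degree diagonal."""

    L: np.ndarray
    D: np.ndarray  # diagonal entries, length m


@dataclass
class SpectralBasis:
    """Eigendecomposition of a Laplacian with optional low-band truncation.

    ``eigenvalues`` ascending; column ``i`` of ``eigenvectors`` pairs with
    ``eigenvalues[i]``.  ``k`` is the selected low-band size (defaults to
    the full basis), ``t_f`` the eigenvalue threshold if the band was chosen
    that way, and ``graph_frequencies`` the per-eigenvector sign-flip counts
    (filled on demand by :func:`graph_frequency`).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k: int | None = None
    t_f: float | None = None
    graph_frequencies: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def U_k(self) -> np.ndarray:
        """First ``k`` eigenvector columns (full basis if ``k`` unset)."""
        k = self.m if self.k is None else self.k
        return self.eigenvectors[:, :k]

    def fingerprint(self) -> str:
        """Stable hash of the eigenvalues, used to detect basis/model
        mismatch when loading checkpoints."""
        import hashlib

        return hashlib.sha256(
            np.ascontiguousarray(self.eigenvalues, dtype=np.float64).tobytes()
        ).hexdigest()[:16]


def laplacian(graph: SourceGraph | np.ndarray) -> Laplacian:
    """``L = D - A`` with ``d_ii = sum_j a_ij``; rows sum to zero."""
    a = graph.adjacency if isinstance(graph, SourceGraph) else np.asarray(graph, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, rtol=0, atol=0):
        raise ValueError("adjacency must be symmetric")
    d = a.sum(axis=1)
    lap = np.diag(d) - a
    return Laplacian(L=lap, D=d)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: the largest-|entry| of each column
    is made positive; among tied magnitudes the lowest index decides."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        idx = int(np.flatnonzero(np.abs(col) == np.abs(col).max())[0])
        if col[idx] < 0:
            v[:, j] = -col
    return v


def eigendecompose(lap: Laplacian | np.ndarray) -> SpectralBasis:
    """Full symmetric eigendecomposition, ascending eigenvalues, with a
    deterministic sign convention so serialized bases are reproducible."""
    mat = lap.L if isinstance(lap, Laplacian) else np.asarray(lap, float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("Laplacian has non-finite entries")
    w, v = scipy.linalg.eigh(mat)
    v = _fix_signs(v)
    return SpectralBasis(eigenvalues=w, eigenvectors=v)


def gft(basis: SpectralBasis, s: np.ndarray) -> np.ndarray:
    """Graph Fourier transform ``U^T s`` (columns of ``s`` are time samples)."""
    s = np.asarray(s, dtype=float)
    if s.shape[0] != basis.m:
        raise ValueError(f"signal has {s.shape[0]} vertices, basis has {basis.m}")
    return basis.eigenvectors.T @ s


def igft(basis: SpectralBasis, coeffs: np.ndarray) -> np.ndarray:
    """Inverse GFT.  Accepts full (length m) coefficients, or truncated
    (length k) coefficients which are expanded with the first ``k``
    eigenvectors — the orthogonal projection onto the low band."""
    coeffs = np.asarray(coeffs, dtype=float)
    m = basis.m
    k = basis.k if basis.k is not None else m
    if coeffs.shape[0] == m:
        return basis.eigenvectors @ coeffs
    if coeffs.shape[0] == k:
        return basis.eigenvectors[:, :k] @ coeffs
    raise ValueError(
        f"coefficient length {coeffs.shape[0]} matches neither m={m} nor k={k}"
    )


def graph_frequency(basis: SpectralBasis, graph: SourceGraph) -> np.ndarray:
    """Sign-flip count per eigenvector: the number of graph edges whose
    endpoint values have strictly opposite signs.  Exact zeros contribute
    no flip.  Fills ``basis.graph_frequencies`` and returns it."""
    if graph.m != basis.m:
        raise ValueError("basis and graph vertex counts differ")
    iu, ju = np.nonzero(np.triu(graph.adjacency > 0, k=1))
    u = basis.eigenvectors
    flips = (u[iu, :] * u[ju, :] < 0).sum(axis=0)
    basis.graph_frequencies = flips.astype(np.int64)
    return basis.graph_frequencies


def select_low_band(
    basis: SpectralBasis, t_f: float | None = None, k: int | None = None
) -> SpectralBasis:
    """Choose the low-frequency band, either by eigenvalue threshold
    (``k = #{lambda_i < t_f}``) or by giving ``k`` directly.  Returns a new
    basis with the truncation recorded."""
    if (t_f is None) == (k is None):
        raise ValueError("give exactly one of t_f or k")
    m = basis.m
    if t_f is not None:
        k_sel = int(np.sum(basis.eigenvalues < t_f))
        if k_sel == 0:
            raise ValueError(
                f"t_f={t_f} is at or below the smallest eigenvalue "
                f"{basis.eigenvalues[0]:.3g}; the band would be empty"
            )
    else:
        if not 1 <= k <= m:
            raise ValueError(f"k must be in [1, {m}], got {k}")
        k_sel = int(k)
    return SpectralBasis(
        eigenvalues=basis.eigenvalues,
        eigenvectors=basis.eigenvectors,
        k=k_sel,
        t_f=t_f,
        graph_frequencies=basis.graph_frequencies,
    )


class GraphLowBandTransform(TransformerMixin, BaseEstimator):
    """Low-band graph Fourier transform as a scikit-learn transformer.

    ``fit`` takes the (m, m) adjacency matrix of the source graph and
    computes the Laplacian eigenbasis; ``transform`` projects vertex-indexed
    signals onto the first ``k`` eigenvectors and ``inverse_transform``
    expands coefficients back to the vertex domain (the orthogonal
    projection onto the low band).

    Parameters
    ----------
    k : int, optional
        Low-band size.  Mutually exclusive with ``t_f`` and ``k_frac``.
    t_f : float, optional
        Eigenvalue threshold; the band keeps eigenvalues strictly below it.
    k_frac : float, default 0.3
        Fraction of the spectrum to keep, ``k = round(k_frac * m)``, used
        when neither ``k`` nor ``t_f`` is given.  The default keeps the
        lowest 30% of the spectrum.
    """

    def __init__(
        self,
        k: int | None = None,
        t_f: float | None = None,
        k_frac: float = 0.3,
    ):
        self.k = k
        self.t_f = t_f
        self.k_frac = k_frac

    def fit(self, X, y=None):
        """Compute the eigenbasis of the Laplacian of adjacency ``X``."""
        if self.k is not None and self.t_f is not None:
            raise ValueError("give at most one of k and t_f")
        basis = eigendecompose(laplacian(np.asarray(X, dtype=float)))
        if self.t_f is not None:
            basis = select_low_band(basis, t_f=self.t_f)
        elif self.k is not None:
            basis = select_low_band(basis, k=self.k)
        else:
            basis = select_low_band(basis, k=max(1, round(self.k_frac * basis.m)))
        self.basis_ = basis
        self.eigenvalues_ = basis.eigenvalues
        self.eigenvectors_ = basis.eigenvectors
        self.k_ = basis.k
        return self

    def transform(self, X):
        """Project signals (m, T) or (n_trials, m, T) onto the low band."""
        X = np.asarray(X, dtype=float)
        u_k = self.basis_.U_k
        if X.ndim == 2:
            return u_k.T @ X
        if X.ndim == 3:
            return np.einsum("mk,bmt->bkt", u_k, X)
        raise ValueError("expected (m, T) or (n_trials, m, T)")

    def inverse_transform(self, X):
        """Expand low-band coefficients (k, T) or (n_trials, k, T)."""
        X = np.asarray(X, dtype=float)
        u_k = self.basis_.U_k
        if X.ndim == 2:
            return u_k @ X
        if X.ndim == 3:
            return np.einsum("mk,bkt->bmt", u_k, X)
        raise ValueError("expected (k, T) or (n_trials, k, T)")
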