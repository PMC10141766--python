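"""Laplacian Eigenmap dimensionality reduction of the feature matrix.

A k-nearest-neighbour graph is built on standardised features, and the
embedding solves the generalized eigenproblem L y = λ D y with
L = D − W the graph Laplacian and D the degree matrix.  The trivial
constant eigenvector (λ = 0) is discarded; the next r eigenvectors are
the coordinates, normalised so that Yᵀ D Y = I.  Out-of-sample points
are mapped by a Nystrom-style weighted average of training coordinates,
so the embedding can sit inside cross-validation without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class NeighborGraph:
    """Symmetric non-negative adjacency with its degree vector."""

    weights: np.ndarray
    n_neighbors: int

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(W < 0) or np.any(np.diag(W) != 0):
            raise ValueError("weights must be non-negative with zero diagonal")
        self.weights = W

    @property
    def degree(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def n_components_graph(self) -> int:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components
        return int(connected_components(csr_matrix(self.weights),
                                        directed=False)[0])


@dataclass
class EmbeddingResult:
    eigenvalues: np.ndarray       # ascending, including the trivial 0
    coordinates: np.ndarray       # trials x r
    r: int


def build_graph(features: np.ndarray, n_neighbors: int = 5,
                weight_scheme: str = "binary", t: float = 1.0) -> NeighborGraph:
    """k-NN graph on row vectors, symmetrised with the OR rule.

    An edge i-j exists iff j is among i's ``n_neighbors`` Euclidean
    nearest neighbours or vice versa; weights are 1 (``binary``) or
    exp(−‖x_i−x_j‖²/t) (``heat``).
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n={n}")
    if weight_scheme not in ("binary", "heat"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    D = cdist(X, X)
    order = np.argsort(D, axis=1)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nn = [j for j in order[i] if j != i][:n_neighbors]
        adj[i, nn] = True
    adj |= adj.T
    if weight_scheme == "binary":
        W = adj.astype(float)
    else:
        W = np.where(adj, np.exp(-D ** 2 / t), 0.0)
    np.fill_diagonal(W, 0.0)
    return NeighborGraph(weights=W, n_neighbors=n_neighbors)


def laplacian_embed(g: NeighborGraph, r: int = 10,
                    strict: bool = False) -> EmbeddingResult:
    """Solve L y = λ D y and return the r smallest nontrivial eigenvectors.

    Eigenvectors come out D-orthonormal (Yᵀ D Y = I).  A disconnected
    graph has one zero eigenvalue per component; all of those indicator
    directions are treated as trivial and skipped, with a warning (or an
    error under ``strict``).
    """
    W = g.weights
    n = W.shape[0]
    if not 1 <= r < n:
        raise ValueError(f"embedding dimension r={r} must be in [1, {n})")
    d = g.degree
    if np.any(d <= 0):
        raise ValueError("graph has isolated vertices (zero degree)")
    L = np.diag(d) - W
    evals, evecs = scipy.linalg.eigh(L, np.diag(d))
    evals = np.clip(evals, -1e-12, None)

    n_zero = int(np.sum(evals < 1e-8 * max(evals.max(), 1.0)))
    n_zero = max(n_zero, 1)
    if n_zero > 1:
        msg = f"graph has {n_zero} connected components"
        if strict:
            raise RuntimeError(msg)
        warnings.warn(msg + "; component-indicator eigenvectors are kept as "
                      "coordinates", RuntimeWarning, stacklevel=2)
    # drop only the first zero eigenvector (the constant direction); extra
    # zero eigenvectors of a disconnected graph are component indicators and
    # carry real structure
    if 1 + r > n:
        raise ValueError("not enough nontrivial eigenvectors for r")
    Y = evecs[:, 1:1 + r]
    return EmbeddingResult(eigenvalues=evals, coordinates=Y, r=r)


class LaplacianEigenmap(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping graph construction + embedding.

    ``fit`` embeds the training set; ``transform`` maps new points by a
    Nystrom-style extension: each test point's coordinate is the
    weighted average of the coordinates of its ``n_neighbors`` nearest
    training points (inverse-distance weights).  ``transform`` on the
    training data itself returns the fitted coordinates.
    """

    def __init__(self, n_neighbors: int = 5, r: int = 10,
                 weight_scheme: str = "binary", t: float = 1.0):
        self.n_neighbors = n_neighbors
        self.r = r
        self.weight_scheme = weight_scheme
        self.t = t

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        r_eff = min(self.r, X.shape[1] - 1 if X.shape[1] > 1 else 1,
                    X.shape[0] - 2)
        graph = build_graph(X, n_neighbors=self.n_neighbors,
                            weight_scheme=self.weight_scheme, t=self.t)
        res = laplacian_embed(graph, r=max(1, r_eff))
        self.train_X_ = X
        self.graph_ = graph
        self.embedding_ = res.coordinates
        self.eigenvalues_ = res.eigenvalues
        self.r_ = res.r
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "embedding_")
        X = np.asarray(X, dtype=float)
        if X.shape == self.train_X_.shape and np.array_equal(X, self.train_X_):
            return self.embedding_
        D = cdist(X, self.train_X_)
        out = np.empty((X.shape[0], self.r_))
        for i in range(X.shape[0]):
            nn = np.argsort(D[i])[:self.n_neighbors]
            w = 1.0 / (D[i, nn] + 1e-12)
            out[i] = (w[:, None] * self.embedding_[nn]).sum(axis=0) / w.sum()
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).embedding_
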