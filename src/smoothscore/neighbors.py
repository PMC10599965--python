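"""Per-group KNN graphs and their conversion to smoothing operators.

Cells are embedded by the standard recipe (depth normalization, log1p,
unit-variance scaling, truncated PCA), linked to their K Euclidean nearest
neighbors, and the directed graph is turned into a symmetric non-negative
adjacency matrix: binary, or weighted by a density-adjusted Gaussian kernel

    w_ij = exp(-d_ij^2 / (sigma_i * sigma_j)),    sigma_i = d(i, K-th neighbor)

with the per-cell bandwidth sigma_i adapting the kernel to local density.
Symmetrization takes the elementwise maximum over the union of directed
edges; the diagonal is fixed at 1 so a cell never loses its own counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datamodel import ExpressionDataset

__all__ = [
    "NeighborGraph",
    "AdjacencyMatrix",
    "embed_cells",
    "build_knn",
    "gaussian_connectivities",
    "binary_adjacency",
    "identity_adjacency",
]

logger = logging.getLogger(__name__)

#: Group sizes up to this use exhaustive all-pairs search with stable
#: lowest-index tie-breaking; larger groups use tree-based exact search.
EXACT_SEARCH_LIMIT = 2048


@dataclass
class NeighborGraph:
    """K nearest neighbors per cell, self excluded, distances ascending."""

    neighbor_indices: np.ndarray  # (n_cells, K) int
    neighbor_distances: np.ndarray  # (n_cells, K) float, sorted per row
    representation_used: str

    @property
    def n_cells(self) -> int:
        return self.neighbor_indices.shape[0]

    @property
    def K(self) -> int:
        return self.neighbor_indices.shape[1]

    def truncated(self, K: int) -> "NeighborGraph":
        """The same graph keeping only each cell's first ``K`` neighbors.

        Exact search lists neighbors in ascending distance with stable
        index tie-breaks, so truncation yields exactly the K-NN graph that
        a direct build with the smaller K would produce.
        """
        if K > self.K:
            raise ValueError(f"cannot truncate K={self.K} graph to K={K}")
        return NeighborGraph(
            self.neighbor_indices[:, :K],
            self.neighbor_distances[:, :K],
            self.representation_used,
        )


@dataclass
class AdjacencyMatrix:
    """Symmetric non-negative smoothing operator with unit diagonal."""

    A: sp.csr_matrix
    mode: str  # binary | connectivity | off


def embed_cells(
    ds: ExpressionDataset | sp.spmatrix | np.ndarray,
    n_components: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Low-dimensional per-cell coordinates for neighbor search.

    Applies total-count normalization to the median depth, log1p, per-gene
    unit-variance scaling (zero-variance genes dropped) and truncated PCA.
    ``n_components`` is clipped to min(n_cells, n_genes) - 1 with a warning
    when too large.
    """
    X = ds.counts if isinstance(ds, ExpressionDataset) else ds
    X = sp.csr_matrix(X, dtype=float) if not sp.issparse(X) else X.tocsr().astype(float)
    n_cells, n_genes = X.shape
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    cap = min(n_cells, n_genes) - 1
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} clipped to {cap} for a "
            f"{n_cells}x{n_genes} matrix"
        )
        n_components = cap
    depths = np.asarray(X.sum(axis=1)).ravel()
    target = np.median(depths[depths > 0]) if (depths > 0).any() else 1.0
    scale = np.divide(target, depths, out=np.zeros_like(depths, dtype=float), where=depths > 0)
    Xn = sp.diags(scale) @ X
    Xn.data = np.log1p(Xn.data)

    dense = np.asarray(Xn.todense())
    var = dense.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError("no variable genes: the counts matrix is constant per gene")
    dense = (dense[:, keep] - dense[:, keep].mean(axis=0)) / np.sqrt(var[keep])
    n_components = min(n_components, min(dense.shape) - 1) or 1
    pca = PCA(n_components=n_components, random_state=seed)
    return pca.fit_transform(dense)


def build_knn(embedding: np.ndarray, K: int, seed: int = 0) -> NeighborGraph:
    """Exact Euclidean K nearest neighbors per cell, excluding self.

    ``K >= group size`` is clipped to ``group size - 1`` with a warning; a
    single-cell group yields a zero-neighbor graph.  Ties are broken toward
    the lower cell index, making the result deterministic; ``seed`` is
    accepted for interface stability (exact search does not use it).
    """
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2:
        raise ValueError("embedding must be 2-D (cells x components)")
    n = emb.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        if n > 1:
            warnings.warn(f"K={K} clipped to {n - 1} for a group of {n} cells")
        K = n - 1
    if K == 0:
        return NeighborGraph(
            np.zeros((n, 0), dtype=int), np.zeros((n, 0)), "euclidean"
        )
    if n <= EXACT_SEARCH_LIMIT:
        d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1) if n <= 64 else None
        if d2 is None:
            from sklearn.metrics import pairwise_distances

            d2 = pairwise_distances(emb, metric="sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        order = np.argsort(d2, axis=1, kind="stable")[:, :K]
        dist = np.sqrt(np.maximum(np.take_along_axis(d2, order, axis=1), 0.0))
    else:
        nn = NearestNeighbors(n_neighbors=K + 1).fit(emb)
        dist_all, order_all = nn.kneighbors(emb)
        order = np.empty((n, K), dtype=int)
        dist = np.empty((n, K))
        rows = np.arange(n)
        for i in rows:
            mask = order_all[i] != i
            if mask.sum() > K:  # self not returned (duplicate points)
                mask[np.flatnonzero(mask)[-1]] = False
            order[i] = order_all[i, mask][:K]
            dist[i] = dist_all[i, mask][:K]
    return NeighborGraph(order, dist, "euclidean")


def _symmetrize(rows, cols, vals, n) -> sp.csr_matrix:
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)
    W = W.tolil()
    W.setdiag(1.0)
    return W.tocsr()


def gaussian_connectivities(g: NeighborGraph) -> AdjacencyMatrix:
    """Density-adjusted Gaussian edge weights from a neighbor graph.

    The local bandwidth ``sigma_i`` is the distance to the K-th listed
    neighbor.  Coincident K-th neighbors (``sigma_i = 0``) borrow the
    smallest positive distance in the group; if every distance is zero the
    weights are uniform 1.
    """
    n, K = g.n_cells, g.K
    if K == 0:
        return identity_adjacency(n, mode="connectivity")
    sigma = g.neighbor_distances[:, -1].astype(float).copy()
    positive = g.neighbor_distances[g.neighbor_distances > 0]
    if positive.size == 0:
        sigma[:] = 1.0  # all-coincident group: uniform weights
        d2 = np.zeros_like(g.neighbor_distances, dtype=float)
    else:
        sigma[sigma == 0] = positive.min()
        d2 = g.neighbor_distances.astype(float) ** 2
    rows = np.repeat(np.arange(n), K)
    cols = g.neighbor_indices.ravel()
    w = np.exp(-(d2.ravel() / (sigma[rows] * sigma[cols])))
    return AdjacencyMatrix(_symmetrize(rows, cols, w, n), "connectivity")


def binary_adjacency(g: NeighborGraph) -> AdjacencyMatrix:
    """0/1 adjacency over the union-symmetrized edge set, unit diagonal."""
    n, K = g.n_cells, g.K
    if K == 0:
        return identity_adjacency(n, mode="binary")
    rows = np.repeat(np.arange(n), K)
    cols = g.neighbor_indices.ravel()
    return AdjacencyMatrix(_symmetrize(rows, cols, np.ones(n * K), n), "binary")


def identity_adjacency(n: int, mode: str = "off") -> AdjacencyMatrix:
    """The do-nothing smoothing operator (smooth_mode=off)."""
    return AdjacencyMatrix(sp.identity(n, format="csr"), mode)
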