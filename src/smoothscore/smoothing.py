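"""Graph smoothing of the counts matrix, M = A @ X, and count thinning.

With a binary adjacency, row i of M is the summed counts of cell i and its
neighbors — a per-cell mini-pseudobulk that raises abundances and breaks
rank ties without collapsing the cell dimension.  An optional row-mean
variant divides each row by the corresponding row sum of A, which matters
for scale-sensitive scores (mean/median/z) but not for rank-based ones when
row sums are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .neighbors import AdjacencyMatrix

__all__ = ["SmoothedMatrix", "smooth_counts", "downsample_counts"]


@dataclass
class SmoothedMatrix:
    """The smoothed cells x genes matrix for one group."""

    M: sp.csr_matrix
    smooth_mode: str
    K_used: int | None
    row_normalized: bool


def smooth_counts(
    A: AdjacencyMatrix,
    X: sp.spmatrix,
    row_normalize: bool = False,
    K_used: int | None = None,
) -> SmoothedMatrix:
    """Compute M = A @ X sparsely; optionally divide rows by A's row sums.

    ``A`` must be square and match X's row count.  The product stays sparse:
    a zero arises only where a cell and all of its neighbors are zero.
    """
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    n = X.shape[0]
    if A.A.shape != (n, n):
        raise ValueError(f"adjacency is {A.A.shape}, counts have {n} rows")
    M = (A.A @ X).tocsr()
    if row_normalize:
        rs = np.asarray(A.A.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        M = sp.diags(1.0 / rs) @ M
        M = M.tocsr()
    return SmoothedMatrix(M, A.mode, K_used, row_normalize)


def downsample_counts(X: sp.spmatrix | np.ndarray, fraction: float, seed: int = 0):
    """Binomially thin integer counts: each count c becomes Binomial(c, f).

    Models shallower sequencing of the same library; the expected total is
    ``fraction`` times the original total.  Defined on integer counts only;
    ``fraction`` must lie in (0, 1], and 1.0 returns the counts unchanged.
    Deterministic for a fixed seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    was_sparse = sp.issparse(X)
    Xs = X.tocsr().copy() if was_sparse else sp.csr_matrix(np.asarray(X))
    if Xs.nnz and not np.allclose(Xs.data, np.round(Xs.data)):
        raise ValueError("downsampling is defined on integer counts only")
    if fraction == 1.0:
        return Xs if was_sparse else np.asarray(Xs.todense())
    rng = np.random.default_rng(seed)
    Xs.data = rng.binomial(Xs.data.astype(np.int64), fraction).astype(Xs.dtype)
    Xs.eliminate_zeros()
    return Xs if was_sparse else np.asarray(Xs.todense())
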