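"""Single-view locally linear embedding machinery.

For each sample, its K nearest neighbors (under L2, L1 or a geodesic
metric) form a *local patch*.  Reconstruction coefficients c_i, summing
to one, express the sample as the best linear combination of its
neighbors; they are obtained from the regularized local Gram system

    M c = 1,    M_kt = (x_i - x_k) . (x_i - x_t),

with ``reg * trace(M)/K`` added to the diagonal when M is singular or
near-singular (K larger than the feature dimension is the common case).
Each patch contributes a (K+1)x(K+1) patch matrix

    L_i = [[1, -c_i^T], [-c_i, c_i c_i^T]]

whose trace form against the low-dimensional patch coordinates equals the
squared reconstruction error there.  Scattering all patch matrices into
global sample positions yields the N x N alignment matrix
L = sum_i S_i L_i S_i^T — symmetric, positive semidefinite, annihilating
the constant vector, and identical to (I - W)^T (I - W) for the sparse
coefficient matrix W.  A plain LLE embedding takes the eigenvectors of L
with the smallest eigenvalues (optionally dropping the near-constant
trivial one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "reconstruction_weights",
    "patch_matrix",
    "alignment_matrix",
    "lle_embed",
    "smallest_eigenvectors",
]

Metric = Literal["l2", "l1", "geodesic"]


@dataclass(frozen=True)
class NeighborGraph:
    K: int
    metric: Metric
    indices: np.ndarray  # (N, K) neighbor indices, self excluded

    def __post_init__(self) -> None:
        n = self.indices.shape[0]
        if self.K >= n:
            raise ValueError(f"K={self.K} must be < N={n}")
        if (self.indices == np.arange(n)[:, None]).any():
            raise ValueError("self-neighbors are not allowed")


def _pairwise(x: np.ndarray, metric: str) -> np.ndarray:
    return cdist(x, x, metric={"l2": "euclidean", "l1": "cityblock"}[metric])


def geodesic_distances(
    x: np.ndarray, base_k: int
) -> np.ndarray:
    """All-pairs shortest-path distances over the symmetrized L2 K-NN graph.

    Edge weights are the Euclidean lengths; raises if the graph is
    disconnected, naming the number of components.
    """
    d2 = _pairwise(np.asarray(x, float), "l2")
    n = d2.shape[0]
    order = np.argsort(d2 + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    nn = order[:, :base_k]
    rows = np.repeat(np.arange(n), base_k)
    graph = sp.csr_matrix((d2[rows, nn.ravel()], (rows, nn.ravel())), shape=(n, n))
    graph = graph.maximum(graph.T)  # symmetrize
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"geodesic base K-NN graph is disconnected ({n_comp} components); "
            "increase K"
        )
    return shortest_path(graph, method="D", directed=False)


def build_neighbor_graph(
    view: np.ndarray,
    K: int,
    metric: Metric = "l2",
    geodesic_base_k: int | None = None,
) -> NeighborGraph:
    """K nearest neighbors per sample, ties broken by lower index.

    For the geodesic metric, distances are shortest-path lengths over the
    symmetrized Euclidean K-NN graph (base graph K defaults to the patch
    K) and neighbors are the K nearest under that metric.
    """
    x = np.asarray(view, dtype=float)
    n = x.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < N={n}")
    if metric == "geodesic":
        d = geodesic_distances(x, geodesic_base_k or K)
    else:
        d = _pairwise(x, metric)
    np.fill_diagonal(d, np.inf)
    # stable argsort on distances -> ties resolved toward lower index
    idx = np.argsort(d, axis=1, kind="stable")[:, :K]
    return NeighborGraph(K=K, metric=metric, indices=idx)


def reconstruction_weights(
    x_i: np.ndarray, neighbors: np.ndarray, reg: float = 0.2
) -> np.ndarray:
    """Coefficients reconstructing x_i from its neighbors, summing to one.

    The local Gram matrix of neighbor-difference vectors is regularized on
    the diagonal by ``reg * trace(M)/K`` (or ``reg`` itself when the trace
    vanishes, e.g. all neighbors coincide with x_i) before solving.
    """
    x_i = np.asarray(x_i, dtype=float)
    z = x_i[None, :] - np.asarray(neighbors, dtype=float)  # (K, m)
    m = z @ z.T
    k = m.shape[0]
    tr = np.trace(m)
    m = m + np.eye(k) * (reg * tr / k if tr > 0 else reg)
    try:
        c = np.linalg.solve(m, np.ones(k))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"local Gram system is singular even with reg={reg}; "
            "try a larger regularization"
        ) from exc
    return c / c.sum()


def patch_matrix(c_i: np.ndarray) -> np.ndarray:
    """(K+1)x(K+1) trace-form encoding of one patch's reconstruction error.

    Index 0 is the center sample, 1..K its neighbors.  For any patch
    coordinate block Y_i = [y_i, y_i1, ..., y_iK],
    trace(Y_i L_i Y_i^T) = ||y_i - sum_j c_j y_ij||^2.
    """
    c = np.asarray(c_i, dtype=float)
    out = np.empty((c.size + 1, c.size + 1))
    out[0, 0] = 1.0
    out[0, 1:] = -c
    out[1:, 0] = -c
    out[1:, 1:] = np.outer(c, c)
    return out


def alignment_matrix(
    view: np.ndarray,
    K: int,
    metric: Metric = "l2",
    reg: float = 0.2,
    graph: NeighborGraph | None = None,
) -> sp.csr_matrix:
    """Global N x N alignment matrix L = sum_i S_i L_i S_i^T (sparse).

    Symmetric, positive semidefinite, row sums zero.
    """
    x = np.asarray(view, dtype=float)
    n = x.shape[0]
    graph = graph or build_neighbor_graph(x, K, metric)
    rows, cols, vals = [], [], []
    for i in range(n):
        nbr = graph.indices[i]
        c = reconstruction_weights(x[i], x[nbr], reg)
        li = patch_matrix(c)
        pos = np.concatenate([[i], nbr])
        rr, cc = np.meshgrid(pos, pos, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(li.ravel())
    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return (L + L.T) * 0.5  # exact symmetry against fp accumulation order


def _canonical_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-magnitude entry is positive."""
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    return vecs * flip


def smallest_eigenvectors(
    L: sp.spmatrix | np.ndarray, d: int, drop_trivial: bool = True
) -> np.ndarray:
    """Orthonormal eigenvectors of the d smallest eigenvalues of symmetric L.

    With ``drop_trivial``, d+1 eigenvectors are computed and the one most
    correlated with the constant vector (the near-null direction every
    alignment matrix possesses) is excluded.
    """
    n = L.shape[0]
    want = d + 1 if drop_trivial else d
    if want > n:
        raise ValueError(f"d={d} too large for N={n}")
    dense = L.toarray() if sp.issparse(L) else np.asarray(L, dtype=float)
    if n <= 1200 or want > n // 4:
        w, v = eigh(dense, subset_by_index=(0, want - 1))
    else:  # large problems: restarted Lanczos with a small negative shift
        w, v = sp.linalg.eigsh(sp.csr_matrix(dense), k=want, sigma=-1e-6, which="LM")
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    if drop_trivial:
        ones = np.ones(n) / np.sqrt(n)
        keep = np.ones(want, dtype=bool)
        keep[np.argmax(np.abs(v.T @ ones))] = False
        v = v[:, keep]
    return _canonical_signs(v[:, :d])


def lle_embed(
    view: np.ndarray,
    d: int,
    K: int,
    metric: Metric = "l2",
    reg: float = 0.2,
    drop_trivial: bool = True,
) -> np.ndarray:
    """Plain single-view LLE embedding: N rows, d orthonormal columns."""
    x = np.asarray(view, dtype=float)
    if d >= x.shape[0]:
        raise ValueError(f"d={d} must be < N={x.shape[0]}")
    L = alignment_matrix(x, K, metric, reg)
    return smallest_eigenvectors(L, d, drop_trivial)
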