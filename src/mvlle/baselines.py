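"""Single-view baselines on concatenated features: PCA and Laplacian eigenmaps.

Multiview methods are conventionally compared against applying a classic
embedding to the horizontal concatenation of all views.  The helpers here
keep per-view column spans so the concatenation is reversible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

__all__ = ["ConcatenatedView", "concat_views", "pca_embed", "le_embed"]


@dataclass(frozen=True)
class ConcatenatedView:
    matrix: np.ndarray
    spans: tuple[tuple[int, int], ...]  # per-view [start, stop) column spans

    def view(self, v: int) -> np.ndarray:
        a, b = self.spans[v]
        return self.matrix[:, a:b]


def concat_views(views: Sequence[np.ndarray]) -> ConcatenatedView:
    """Horizontal concatenation in declared view order, spans recorded."""
    mats = [np.asarray(v, dtype=float) for v in views]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("views must share the sample count")
    widths = [m.shape[1] for m in mats]
    stops = np.cumsum(widths)
    spans = tuple(
        (int(stop - w), int(stop)) for w, stop in zip(widths, stops)
    )
    return ConcatenatedView(matrix=np.hstack(mats), spans=spans)


def pca_embed(data: np.ndarray, d: int) -> np.ndarray:
    """Projection onto the top-d principal components (mean-centered, unscaled)."""
    x = np.asarray(data, dtype=float)
    if d > min(x.shape):
        raise ValueError(f"d={d} exceeds min(N, width)={min(x.shape)}")
    return PCA(n_components=d, svd_solver="full").fit_transform(x)


def le_embed(
    data: np.ndarray, d: int, K: int, heat_width: float | None = None
) -> np.ndarray:
    """Laplacian eigenmaps on the symmetrized Euclidean K-NN graph.

    Edge weights are the heat kernel exp(-dist^2 / width); ``heat_width``
    defaults to the median squared neighbor distance.  Coordinates are the
    generalized eigenvectors of (L, D) for the smallest nonzero
    eigenvalues — the constant vector (eigenvalue 0) is excluded.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be < N={n}")
    dist = cdist(x, x)
    np.fill_diagonal(dist, np.inf)
    nn = np.argsort(dist, axis=1, kind="stable")[:, :K]
    rows = np.repeat(np.arange(n), K)
    dnn = dist[rows, nn.ravel()]
    if heat_width is None:
        heat_width = float(np.median(dnn**2))
        if heat_width == 0:
            heat_width = 1.0
    # connectivity is a property of the K-NN graph structure; heat-kernel
    # weights of long bridges may underflow to zero, so check it unweighted
    adj = sp.csr_matrix((np.ones_like(dnn), (rows, nn.ravel())), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(f"K-NN graph is disconnected ({n_comp} components)")
    wgt = np.exp(-(dnn**2) / heat_width)
    W = sp.csr_matrix((wgt, (rows, nn.ravel())), shape=(n, n))
    W = W.maximum(W.T)
    Wd = W.toarray()
    deg = Wd.sum(axis=1)
    L = np.diag(deg) - Wd
    evals, evecs = eigh(L, np.diag(deg), subset_by_index=(0, d))
    # first generalized eigenvector is the constant (eigenvalue 0)
    Y = evecs[:, 1 : d + 1]
    flip = np.sign(Y[np.argmax(np.abs(Y), axis=0), np.arange(Y.shape[1])])
    flip[flip == 0] = 1.0
    return Y * flip
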