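"""Multiview LLE: weighted alignment and alternating optimization.

Given per-view alignment matrices L^v (one LLE alignment per feature
representation), the method seeks a single embedding Y (N x d, orthonormal
columns) and a weight vector alpha on the V-simplex minimizing

    sum_v alpha_v^r * trace(Y^T L^v Y),    r > 1.

Without the exponent the optimum is degenerate: all weight collapses onto
the single view with the smallest trace and the remaining views are
discarded.  With r > 1 the two blocks each admit an exact minimizer and
are alternated:

Step 1 (alpha fixed):  Y = eigenvectors of sum_v alpha_v^r L^v for the d
smallest eigenvalues (optionally excluding the near-constant trivial
direction common to all alignment matrices).

Step 2 (Y fixed):  with t_v = trace(Y^T L^v Y),

    alpha_v = (1/t_v)^{1/(r-1)} / sum_u (1/t_u)^{1/(r-1)},

the closed-form stationary point of the Lagrangian on the simplex.
Because both steps are exact conditional minimizers the recorded
objective is non-increasing.  As r -> 1+ the weights concentrate on the
smallest-trace view; as r -> infinity they approach uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .lle import Metric, alignment_matrix, smallest_eigenvectors

__all__ = [
    "ViewWeights",
    "EmbeddingResult",
    "combined_alignment",
    "update_embedding",
    "update_weights",
    "objective",
    "fit",
]

TRACE_FLOOR = 1e-12


@dataclass(frozen=True)
class ViewWeights:
    """Simplex-constrained per-view contributions with smoothing exponent r."""

    alpha: np.ndarray
    r: float = 2.5

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", a)
        if self.r <= 1:
            raise ValueError(
                f"r={self.r} must be > 1: at r <= 1 the weight optimum "
                "degenerates to selecting the single smallest-trace view "
                "and all other views are discarded"
            )
        if (a < -1e-12).any() or abs(a.sum() - 1.0) > 1e-8:
            raise ValueError("alpha must be nonnegative and sum to 1")


@dataclass
class EmbeddingResult:
    Y: np.ndarray
    weights: ViewWeights
    objective_history: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def combined_alignment(
    alignments: Sequence[sp.spmatrix], weights: ViewWeights
) -> sp.csr_matrix:
    """sum_v alpha_v^r L^v — symmetric PSD, annihilates the ones vector."""
    n = alignments[0].shape[0]
    if any(a.shape != (n, n) for a in alignments):
        raise ValueError("alignment matrices must share shape")
    if len(alignments) != weights.alpha.size:
        raise ValueError("one weight per view required")
    out = sp.csr_matrix((n, n))
    for a, w in zip(alignments, weights.alpha):
        out = out + (w**weights.r) * sp.csr_matrix(a)
    return out


def update_embedding(
    Lsum: sp.spmatrix | np.ndarray, d: int, drop_trivial: bool = True
) -> np.ndarray:
    """Exact minimizer of trace(Y^T Lsum Y) over orthonormal N x d frames."""
    return smallest_eigenvectors(Lsum, d, drop_trivial)


def view_traces(Y: np.ndarray, alignments: Sequence[sp.spmatrix]) -> np.ndarray:
    """t_v = trace(Y^T L^v Y) per view."""
    return np.array([float(np.sum(Y * (a @ Y))) for a in alignments])


def update_weights(
    Y: np.ndarray, alignments: Sequence[sp.spmatrix], r: float
) -> ViewWeights:
    """Closed-form simplex weights from the per-view traces.

    Traces are floored at a small epsilon before inversion; if every view
    reconstructs perfectly (all traces at the floor) the weights fall back
    to uniform with a warning.
    """
    t = view_traces(Y, alignments)
    if (t < -1e-8).any():
        raise ValueError("negative view trace: alignment matrix not PSD?")
    if (t <= TRACE_FLOOR).all():
        warnings.warn(
            "all view traces are at the numerical floor; using uniform weights",
            stacklevel=2,
        )
        alpha = np.full(t.size, 1.0 / t.size)
        return ViewWeights(alpha=alpha, r=r)
    # (1/t)^{1/(r-1)} computed in log space: near r=1 the exponent is huge
    # and direct powers overflow long before the ratio does
    log_inv = -np.log(np.maximum(t, TRACE_FLOOR)) / (r - 1.0)
    log_inv -= log_inv.max()
    inv = np.exp(log_inv)
    return ViewWeights(alpha=inv / inv.sum(), r=r)


def objective(
    Y: np.ndarray, alignments: Sequence[sp.spmatrix], weights: ViewWeights
) -> float:
    """sum_v alpha_v^r trace(Y^T L^v Y), always >= 0 for PSD alignments."""
    t = view_traces(Y, alignments)
    return float(np.sum(weights.alpha**weights.r * t))


def fit(
    views: Sequence[np.ndarray],
    d: int = 200,
    K: int = 140,
    r: float = 2.5,
    metric: Metric = "l2",
    reg: float = 0.2,
    max_iter: int = 50,
    tol: float = 1e-6,
    drop_trivial: bool = True,
    seed: int | None = None,
) -> EmbeddingResult:
    """Alternately optimize the shared embedding and the view weights.

    Starts from uniform weights; stops when the largest absolute weight
    change falls below ``tol`` or the relative objective change below
    1e-8, else after ``max_iter`` iterations with ``converged=False``.
    Defaults (d=200, K=140, r=2.5) suit collections of thousands of
    images and are clamped, with a warning, on smaller data.

    ``seed`` is accepted for pipeline plumbing; the optimization itself is
    deterministic (eigenvector signs are canonicalized).
    """
    views = [np.asarray(v, dtype=float) for v in views]
    n = views[0].shape[0]
    if any(v.shape[0] != n for v in views):
        raise ValueError("all views must share the sample count and order")
    if r <= 1:
        ViewWeights(alpha=np.full(len(views), 1.0 / len(views)), r=r)  # raises
    if d >= n:
        warnings.warn(f"d={d} clamped to N-1={n - 1}", stacklevel=2)
        d = n - 1
    if K >= n:
        warnings.warn(f"K={K} clamped to N-1={n - 1}", stacklevel=2)
        K = n - 1
    if drop_trivial and d >= n:
        d = n - 1

    alignments = [alignment_matrix(v, K, metric, reg) for v in views]
    V = len(views)
    weights = ViewWeights(alpha=np.full(V, 1.0 / V), r=r)
    history: list[float] = []
    Y = np.empty((n, d))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = update_embedding(combined_alignment(alignments, weights), d, drop_trivial)
        new_weights = update_weights(Y, alignments, r)
        history.append(objective(Y, alignments, new_weights))
        delta = np.max(np.abs(new_weights.alpha - weights.alpha))
        weights = new_weights
        if delta < tol:
            converged = True
            break
        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if abs(prev - cur) <= 1e-8 * max(abs(prev), 1e-30):
                converged = True
                break
    return EmbeddingResult(
        Y=Y,
        weights=weights,
        objective_history=history,
        iterations=it,
        converged=converged,
    )
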