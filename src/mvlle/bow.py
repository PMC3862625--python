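"""Dense local descriptors and bag-of-visual-words histograms.

Patches are sampled on a regular lattice (default: 16x16 patches every 8
pixels), described either by a 128-D SIFT-style gradient histogram or by
the raw 256-D pixel intensities, and quantized against a K-means codebook
(default 500 words, 100 Lloyd iterations) learned over descriptors pooled
from the whole collection.  Per-image (or per-grid-region) features are
the L1-normalized histograms of nearest-word assignments.

The SIFT-style descriptor follows the standard recipe: 4x4 spatial cells
times 8 orientation bins of gradient magnitude, Gaussian-weighted with
sigma equal to half the patch width, L2-normalized, components clipped at
0.2 and renormalized.  No keypoint detection or scale selection is
performed — sampling is dense by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .lbp import grid_region_edges

__all__ = [
    "DenseSamplingConfig",
    "Codebook",
    "dense_sample",
    "sift_descriptor",
    "intensity_descriptor",
    "patch_descriptors",
    "kmeans_dictionary",
    "bow_histogram",
    "grid_bow_feature",
]


@dataclass(frozen=True)
class DenseSamplingConfig:
    step: int = 8
    patch_size: int = 16

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.patch_size < 4:
            raise ValueError("patch_size must be >= 4")


@dataclass(frozen=True)
class Codebook:
    """K-means visual-word dictionary (k centroid descriptors)."""

    words: np.ndarray  # (k, descriptor_dim)
    descriptor_kind: Literal["sift", "intensity"]

    def __post_init__(self) -> None:
        if self.words.ndim != 2 or self.words.shape[0] < 2:
            raise ValueError("codebook needs at least 2 words")

    @property
    def k(self) -> int:
        return self.words.shape[0]

    @property
    def dim(self) -> int:
        return self.words.shape[1]


def dense_sample(
    image: np.ndarray, cfg: DenseSamplingConfig | None = None
) -> list[tuple[int, int]]:
    """Top-left coordinates of a regular patch lattice, fully inside the image."""
    cfg = cfg or DenseSamplingConfig()
    h, w = np.asarray(image).shape
    if h < cfg.patch_size or w < cfg.patch_size:
        warnings.warn(
            f"image {h}x{w} smaller than patch size {cfg.patch_size}; "
            "no patches sampled",
            stacklevel=2,
        )
        return []
    rows = range(0, h - cfg.patch_size + 1, cfg.step)
    cols = range(0, w - cfg.patch_size + 1, cfg.step)
    return [(r, c) for r in rows for c in cols]


def sift_descriptor(patch: np.ndarray, n_cells: int = 4, n_orient: int = 8) -> np.ndarray:
    """128-D gradient-orientation histogram descriptor of a square patch.

    A constant patch has no gradient energy and yields the zero vector;
    every other patch is L2-normalized (clip at 0.2, renormalize).
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"patch must be square, got shape {p.shape}")
    side = p.shape[0]
    if side % n_cells:
        raise ValueError(f"patch side {side} not divisible into {n_cells} cells")
    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    # Gaussian spatial weighting centred on the patch, sigma = side/2
    yy, xx = np.mgrid[0:side, 0:side] - (side - 1) / 2.0
    weight = np.exp(-(xx**2 + yy**2) / (2.0 * (side / 2.0) ** 2))
    wmag = mag * weight
    obin = np.minimum((ori / (2.0 * np.pi) * n_orient).astype(int), n_orient - 1)
    cell = side // n_cells
    desc = np.zeros((n_cells, n_cells, n_orient))
    for i in range(n_cells):
        for j in range(n_cells):
            sl = np.s_[i * cell : (i + 1) * cell, j * cell : (j + 1) * cell]
            desc[i, j] = np.bincount(
                obin[sl].ravel(), weights=wmag[sl].ravel(), minlength=n_orient
            )
    v = desc.ravel()
    norm = np.linalg.norm(v)
    if norm == 0:
        return v
    v = np.minimum(v / norm, 0.2)
    return v / np.linalg.norm(v)


def intensity_descriptor(patch: np.ndarray) -> np.ndarray:
    """Row-major flattening of the raw pixel values (256-D for 16x16)."""
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2:
        raise ValueError("patch must be 2-D")
    return p.ravel().copy()


def patch_descriptors(
    image: np.ndarray,
    kind: Literal["sift", "intensity"],
    cfg: DenseSamplingConfig | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Descriptors of all densely sampled patches plus their coordinates."""
    cfg = cfg or DenseSamplingConfig()
    img = np.asarray(image, dtype=float)
    coords = dense_sample(img, cfg)
    fn = sift_descriptor if kind == "sift" else intensity_descriptor
    if not coords:
        dim = 128 if kind == "sift" else cfg.patch_size**2
        return np.empty((0, dim)), coords
    descs = np.stack(
        [fn(img[r : r + cfg.patch_size, c : c + cfg.patch_size]) for r, c in coords]
    )
    return descs, coords


def kmeans_dictionary(
    descriptors: np.ndarray,
    k: int = 500,
    max_iter: int = 100,
    seed: int = 0,
    descriptor_kind: Literal["sift", "intensity"] = "sift",
) -> Codebook:
    """Learn a visual-word codebook with Lloyd's K-means.

    Initial centers are k distinct descriptors drawn from a seeded RNG, so
    a fixed seed reproduces the codebook exactly and ``k == #distinct``
    reaches zero inertia.
    """
    x = np.asarray(descriptors, dtype=float)
    distinct = np.unique(x, axis=0)
    if distinct.shape[0] < k:
        raise ValueError(
            f"need at least k={k} distinct descriptors, got {distinct.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    init = distinct[rng.choice(distinct.shape[0], size=k, replace=False)]
    km = KMeans(
        n_clusters=k, init=init, n_init=1, max_iter=max_iter, algorithm="lloyd"
    ).fit(x)
    return Codebook(words=km.cluster_centers_, descriptor_kind=descriptor_kind)


def bow_histogram(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """L1-normalized histogram of nearest-word assignments (ties -> lowest index)."""
    x = np.asarray(descriptors, dtype=float)
    if x.shape[0] == 0:
        warnings.warn("empty descriptor set; returning zero histogram", stacklevel=2)
        return np.zeros(codebook.k)
    if x.shape[1] != codebook.dim:
        raise ValueError(
            f"descriptor dim {x.shape[1]} != codebook dim {codebook.dim}"
        )
    assign = np.argmin(cdist(x, codebook.words), axis=1)
    counts = np.bincount(assign, minlength=codebook.k)
    return counts / counts.sum()


def grid_bow_feature(
    image: np.ndarray,
    g: int,
    codebook: Codebook,
    cfg: DenseSamplingConfig | None = None,
) -> np.ndarray:
    """Concatenated per-region BoW histograms (patch assigned by its top-left).

    Regions too small to contain any patch top-left contribute a zero
    histogram.  Output length is ``g*g*k``.
    """
    cfg = cfg or DenseSamplingConfig()
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    kind = codebook.descriptor_kind
    descs, coords = patch_descriptors(img, kind, cfg)
    rows = grid_region_edges(h, g)
    cols = grid_region_edges(w, g)
    blocks = []
    coords_arr = np.asarray(coords) if coords else np.empty((0, 2), dtype=int)
    for r0, r1 in rows:
        for c0, c1 in cols:
            inside = (
                (coords_arr[:, 0] >= r0)
                & (coords_arr[:, 0] < r1)
                & (coords_arr[:, 1] >= c0)
                & (coords_arr[:, 1] < c1)
            ) if coords_arr.size else np.zeros(0, dtype=bool)
            if inside.any():
                blocks.append(bow_histogram(descs[inside], codebook))
            else:
                warnings.warn(
                    f"region ({r0}:{r1},{c0}:{c1}) holds no patch; zero histogram",
                    stacklevel=2,
                )
                blocks.append(np.zeros(codebook.k))
    return np.concatenate(blocks)
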