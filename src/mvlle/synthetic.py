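"""Synthetic multiview and texture-image generators with known ground truth.

Two generators cover the two kinds of input the rest of the package
consumes:

``gen_multiview_manifold``
    V feature matrices observed from a *shared* low-dimensional latent
    manifold through per-view linear or swiss-roll-style nonlinear maps,
    with per-view additive i.i.d. Gaussian noise.  Because every view is a
    noisy image of the same latent coordinates, the informativeness of a
    view is controlled purely by its noise level — exactly the situation in
    which the multiview embedding's view weights should favour the cleaner
    view.

``gen_texture_images``
    Labeled 8-bit grayscale images whose classes are distinct procedural
    textures (oriented sinusoidal gratings with class-specific frequency
    and orientation plus seeded noise), so texture descriptors such as LBP
    histograms and bag-of-visual-words features are class-discriminative.

Everything is driven by :class:`numpy.random.Generator` seeded from the
spec, so a fixed seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LatentManifoldSpec",
    "TextureImageSpec",
    "ViewSpec",
    "gen_multiview_manifold",
    "gen_texture_images",
]

MapKind = Literal["linear", "swiss-roll"]


@dataclass(frozen=True)
class ViewSpec:
    """One observed view of the latent manifold.

    Parameters
    ----------
    ambient_dim:
        Dimension of the observed feature space; must be at least the
        latent dimension.
    map_kind:
        ``"linear"`` for a random full-rank linear map, ``"swiss-roll"``
        for the classical curl of the first two latent coordinates
        followed by a random linear lift.
    noise_sd:
        Standard deviation of the additive i.i.d. Gaussian noise.
    """

    ambient_dim: int
    map_kind: MapKind = "linear"
    noise_sd: float = 0.0


@dataclass(frozen=True)
class LatentManifoldSpec:
    n_samples: int
    latent_dim: int
    view_specs: Sequence[ViewSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if not self.view_specs:
            raise ValueError("at least one view is required")
        for v, vs in enumerate(self.view_specs):
            if vs.ambient_dim < self.latent_dim:
                raise ValueError(
                    f"view {v}: ambient_dim {vs.ambient_dim} < latent_dim "
                    f"{self.latent_dim}"
                )
            if vs.noise_sd < 0:
                raise ValueError(f"view {v}: noise_sd must be nonnegative")
            if vs.map_kind not in ("linear", "swiss-roll"):
                raise ValueError(f"view {v}: unknown map_kind {vs.map_kind!r}")


@dataclass(frozen=True)
class TextureImageSpec:
    n_classes: int
    per_class: int
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.per_class < 1:
            raise ValueError("n_classes and per_class must be positive")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")


def _latent_coordinates(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    # First latent coordinate plays the role of the swiss-roll angle; a
    # range of [1.5pi, 4.5pi] gives the canonical curl without self-overlap.
    z = rng.uniform(0.0, 1.0, size=(n, dim))
    z[:, 0] = 1.5 * np.pi + 3.0 * np.pi * z[:, 0]
    return z


def _view_map(
    rng: np.random.Generator, z: np.ndarray, vs: ViewSpec
) -> np.ndarray:
    n, latent_dim = z.shape
    if vs.map_kind == "linear":
        a = rng.standard_normal((latent_dim, vs.ambient_dim))
        return z @ a
    # swiss-roll: curl first coordinate, keep the rest, lift linearly
    t = z[:, 0]
    rolled = np.column_stack([t * np.cos(t), t * np.sin(t), z[:, 1:]])
    lift = rng.standard_normal((rolled.shape[1], vs.ambient_dim))
    return rolled @ lift


def gen_multiview_manifold(
    spec: LatentManifoldSpec,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate V noisy views of one latent manifold.

    Returns
    -------
    views:
        List of ``n_samples x ambient_dim_v`` float arrays sharing sample
        order across views.
    latent:
        The ``n_samples x latent_dim`` latent coordinates the views were
        generated from (ground truth for neighborhood checks).
    """
    root = np.random.SeedSequence(spec.seed)
    latent_ss, *view_ss = root.spawn(1 + len(spec.view_specs))
    latent = _latent_coordinates(
        np.random.default_rng(latent_ss), spec.n_samples, spec.latent_dim
    )
    views: list[np.ndarray] = []
    for vs, ss in zip(spec.view_specs, view_ss):
        rng = np.random.default_rng(ss)
        x = _view_map(rng, latent, vs)
        if vs.noise_sd > 0:
            x = x + rng.normal(0.0, vs.noise_sd, size=x.shape)
        views.append(x)
    return views, latent


def gen_texture_images(
    spec: TextureImageSpec,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate labeled grayscale texture images.

    Each class is an oriented sinusoidal grating with a class-specific
    spatial frequency and orientation; each image gets a random phase and
    mild pixel noise so images within a class vary.  Pixel values are
    uint8 in [0, 255]; labels are ints aligned with the image list.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    images: list[np.ndarray] = []
    labels = np.repeat(np.arange(spec.n_classes), spec.per_class)
    for c in range(spec.n_classes):
        # frequencies in cycles/pixel well inside Nyquist; orientations
        # spread over [0, pi)
        freq = 0.08 + 0.06 * c
        theta = np.pi * c / max(spec.n_classes, 1)
        for _ in range(spec.per_class):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = np.sin(
                2.0 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta))
                + phase
            )
            img = 127.5 + 90.0 * wave + rng.normal(0.0, 8.0, size=(h, w))
            images.append(np.clip(img, 0, 255).astype(np.uint8))
    return images, labels
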