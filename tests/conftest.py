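import numpy as np
import pytest

from mvlle.synthetic import (
    LatentManifoldSpec,
    TextureImageSpec,
    ViewSpec,
    gen_multiview_manifold,
    gen_texture_images,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def manifold_views():
    """Two linear views of one 2-D latent manifold: clean and noisy."""
    spec = LatentManifoldSpec(
        n_samples=150,
        latent_dim=2,
        view_specs=(
            ViewSpec(ambient_dim=20, noise_sd=0.0),
            ViewSpec(ambient_dim=20, noise_sd=5.0),
        ),
        seed=3,
    )
    views, latent = gen_multiview_manifold(spec)
    return views, latent


@pytest.fixture(scope="session")
def texture_set():
    """Small two-class texture image set with labels."""
    images, labels = gen_texture_images(
        TextureImageSpec(n_classes=2, per_class=8, image_size=(64, 64), seed=5)
    )
    return images, labels
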