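import numpy as np
import pytest

from impressionface.synthetic_faces import (
    FaceTemplate,
    RatingSimConfig,
    build_template,
    default_shape_sim_config,
    simulate_ratings,
    simulate_shapes,
)


@pytest.fixture(scope="session")
def template() -> FaceTemplate:
    return build_template()


@pytest.fixture(scope="session")
def small_study(template):
    """A 40-face, 12-rater synthetic study shared by fast tests."""
    cfg = default_shape_sim_config(template, n_faces=40, seed=11)
    configs, latent = simulate_shapes(template, cfg)
    ratings = simulate_ratings(latent, RatingSimConfig(n_raters=12, seed=12))
    return {"cfg": cfg, "configs": configs, "latent": latent, "ratings": ratings}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
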