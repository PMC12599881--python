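import numpy as np
import pytest

from axoshed.config import SceneConfig


@pytest.fixture
def small_cfg():
    """A small, fast scene: 40 particles on a 100 um field."""
    return SceneConfig(n_particles=40, field_length_um=100.0, seed=7)


@pytest.fixture
def one_particle_cfg():
    """Degenerate scene with one stationary particle and no noise terms."""
    return SceneConfig(
        n_particles=1, field_length_um=40.0, n_axons=1, n_frames=20,
        state_fractions=(1.0, 0.0, 0.0), stationary_jitter_um=0.0,
        noise_model={"gaussian_sd": 0.0, "poisson_scale": 0.0}, seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
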