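import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_set():
    """A small deterministic set of reduced-size patches for fast
    training-loop tests (full-size patches are exercised elsewhere)."""
    from nodseg.phantom_generator import PhantomConfig, generate_patches

    cfg = PhantomConfig(n_patches=12, patch_shape=(8, 32, 32),
                        diameter_range_mm=(3.0, 12.0), fraction_empty=0.25,
                        seed=42)
    return [pair for pair, _ in generate_patches(cfg)]


@pytest.fixture(scope="session")
def tiny_net_cfg():
    from nodseg.unet3d import NetworkConfig

    return NetworkConfig(base_channels=4, variant="enhanced",
                         attention_cfg={"cbam_reduction": 4, "se_reduction": 4},
                         seed=0)
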