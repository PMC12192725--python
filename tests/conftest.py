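import numpy as np
import pytest

from rmisnet import ModelConfig, SynthConfig, build_model, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """Small channel widths so forward/backward stay fast in unit tests."""
    return ModelConfig(channels=(4, 8, 12, 16, 24))


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def blob_set():
    """Sixteen 64x64 synthetic blob pairs (images (3,H,W), exact masks)."""
    cfg = SynthConfig(n_images=16, image_size=(64, 64), seed=0)
    samples = [generate_sample(cfg, i) for i in range(cfg.n_images)]
    images = np.stack([s[0] for s in samples])
    masks = np.stack([s[1] for s in samples])
    return images, masks
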