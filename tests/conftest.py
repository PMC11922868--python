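import numpy as np
import pytest

from hatrans.config import GeneratorConfig, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def micro_config():
    """Smallest viable model: 16×16 images, 4 patches, 2 layers."""
    return ModelConfig(image_size=16, patch_size=8, embed_dim=16, depth=2,
                       num_heads=2, num_labels=4, variant="tiny")


@pytest.fixture
def tiny_config():
    return ModelConfig.from_variant("tiny")


@pytest.fixture
def gen_config():
    return GeneratorConfig(n_images=24, image_size=32, seed=7)


def random_attention_stack(rng, layers, batch, heads, tokens):
    """Random row-stochastic attention stack L×B×h×T×T."""
    raw = rng.random((layers, batch, heads, tokens, tokens)) + 1e-3
    return raw / raw.sum(axis=-1, keepdims=True)
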