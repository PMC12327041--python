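import numpy as np
import pytest

from grotunet.config import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(input_size=(32, 32), **overrides) -> ModelConfig:
    """A minimal-width model configuration for fast structural tests."""
    base = dict(
        input_size=input_size,
        stage_widths=(8, 8, 12, 16),
        gr_branch_width=4,
        wgr_branch_widths=(4, 4, 4),
        token_dim=16,
        heads=4,
        outlook_depth=1,
        transformer_depth=1,
        outlook_mlp_hidden=16,
        transformer_mlp_hidden=16,
        skip_widths=(6, 8),
        decoder_widths=(12, 10, 8, 8),
        lateral_width=4,
        plain_decoder_widths=(12, 10, 8, 8),
        embedding_dim=4,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def tiny_cfg():
    return tiny_config()


def zero_params(module) -> None:
    """Zero every trainable parameter of a module (including BN scale)."""
    for p in module.parameters():
        p.data[...] = 0.0
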