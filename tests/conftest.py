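import numpy as np
import pytest

from biaae import (ArchSpec, FactorSpec, ModelConfig, PatternPairSpec,
                   build_model, generate_factor_pairs, generate_pattern_pairs)


@pytest.fixture(scope="session")
def factor_spec():
    return FactorSpec(dim_s=2, dim_zx=3, dim_zy=3, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def factor_samples(factor_spec):
    return generate_factor_pairs(factor_spec, 256)


@pytest.fixture(scope="session")
def pattern_spec():
    return PatternPairSpec(n_classes=4, image_side=12, noise_sd=0.5,
                           n_samples=200, seed=5)


@pytest.fixture(scope="session")
def pattern_samples(pattern_spec):
    return generate_pattern_pairs(pattern_spec)


@pytest.fixture()
def small_config(factor_spec):
    return ModelConfig(
        variant="biaae", x_dim=factor_spec.dim_x, y_dim=factor_spec.dim_y,
        dim_zx=3, dim_s=2, dim_zy=3,
        encoder_arch=ArchSpec(hidden=(16,)),
        decoder_arch=ArchSpec(hidden=(16,)),
        discriminator_arch=ArchSpec(hidden=(16,)),
        seed=3,
    )


@pytest.fixture()
def small_model(small_config):
    return build_model(small_config)


@pytest.fixture(scope="session")
def toy_smiles():
    """Small valid molecules used across tokenizer/metric tests."""
    return [
        "CCO", "CCN", "c1ccccc1", "CC(=O)O", "c1ccccc1Cl", "CCBr",
        "c1ccncc1", "CC(C)O", "CC#N", "OCC(O)CO",
    ]
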