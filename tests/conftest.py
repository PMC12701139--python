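import numpy as np
import pytest

from adrenalseg import (
    MaskVolume,
    NoisyOracleSpec,
    PhantomSpec,
    generate_phantom,
    make_noisy_oracle,
    preprocess_volume,
)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic phantom (CT volume, gland mask)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def preprocessed_phantom(phantom_pair):
    vol, mask = phantom_pair
    return preprocess_volume(vol), mask


@pytest.fixture(scope="session")
def clean_oracle(preprocessed_phantom):
    pre, mask = preprocessed_phantom
    spec = NoisyOracleSpec(boundary_noise_sd=0.0, fp_blob_rate=0.0, fn_dropout=0.0)
    return make_noisy_oracle(mask, spec, pre)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mask(rng, shape=(6, 8, 8), p=0.3):
    return MaskVolume((rng.random(shape) < p).astype(np.uint8))
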