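import numpy as np
import pytest

import histokey as hk
from histokey.synthetic import DEFAULT_CLASSES, make_patch


@pytest.fixture(scope="session")
def texture_patches():
    """20 deterministic patches of each default texture class."""
    return {
        spec.class_id: [make_patch(spec, seed=1000 * spec.class_id + i) for i in range(20)]
        for spec in DEFAULT_CLASSES
    }


@pytest.fixture(scope="session")
def all_patches(texture_patches):
    return [p for ps in texture_patches.values() for p in ps]


@pytest.fixture(scope="session")
def trained_ae(all_patches):
    """A small autoencoder trained briefly on mixed texture patches."""
    return hk.PatchAutoencoder(
        latent_dim=64, epochs=3, batch_size=32, random_state=0
    ).fit(all_patches)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_raster(h, w, seed=0, lo=60, hi=230):
    """Random textured RGB raster that passes brightness/variance QC."""
    r = np.random.default_rng(seed)
    return r.integers(lo, hi, size=(h, w, 3), dtype=np.uint8)
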