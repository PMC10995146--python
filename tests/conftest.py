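import numpy as np
import pytest

from dmif.phantoms import PhantomSpec, make_phantom_pair, tiny_backbone


@pytest.fixture(scope="session")
def backbone():
    return tiny_backbone(seed=0)


@pytest.fixture(scope="session")
def ct_mri_64():
    """One seeded registered CT/MRI-like pair at 64x64."""
    return make_phantom_pair(PhantomSpec(size=(64, 64), modality_pair="ct_mri", seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
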