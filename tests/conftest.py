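import numpy as np
import pytest

from drdseg.phantoms import NoiseSpec, corrupt, generate_phantom


@pytest.fixture(scope="session")
def speckle_phantom():
    """84x84 phantom with two lesions plus its speckle-corrupted version (sigma 0.2)."""
    phantom = generate_phantom((84, 84), n_lesions=2, contrast=0.4, seed=7)
    noisy = corrupt(phantom.image, NoiseSpec(model="multiplicative_speckle", sigma=0.2, seed=8))
    return phantom, np.clip(noisy, 0.0, None)


@pytest.fixture(scope="session")
def phantom_batch():
    """Eight small single-lesion phantoms for training tests."""
    images, masks = [], []
    for s in range(8):
        ph = generate_phantom((32, 32), n_lesions=1, contrast=0.4, seed=100 + s)
        images.append(ph.image)
        masks.append(ph.mask)
    return np.stack(images), np.stack(masks)
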