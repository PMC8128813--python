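import numpy as np
import pytest

import habitatmap as hm


@pytest.fixture(scope="session")
def small_spec():
    """Compact 3-habitat phantom geometry used by fast unit tests."""
    return hm.PhantomSpec(
        shape=(6, 40, 40), spacing=(1.0, 1.0, 3.0),
        semi_axes_mm=(14.0, 14.0, 7.0), seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return hm.make_phantom(small_spec)


@pytest.fixture(scope="session")
def omental_phantom():
    return hm.make_phantom(
        hm.PhantomSpec(
            shape=(6, 40, 40), spacing=(1.0, 1.0, 3.0),
            semi_axes_mm=(14.0, 14.0, 7.0),
            site="omentum", fat_fraction=0.3, seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_volume():
    """A 20x20x3 lesion with two texture regions, small enough for
    brute-force per-voxel oracles."""
    rng = np.random.default_rng(99)
    vox = np.full((3, 20, 20), 40.0)
    vox[:, :, :10] = 50.0 + 25.0 * rng.standard_normal((3, 20, 10))
    vox[:, :, 10:] = 80.0 + 5.0 * rng.standard_normal((3, 20, 10))
    volume = hm.ImageVolume(voxels=vox, spacing=np.array([1.0, 1.0, 3.0]))
    mask = np.zeros((3, 20, 20), dtype=bool)
    mask[:, 2:18, 2:18] = True
    return volume, hm.VOIMask(voxels=mask, reference_shape=(3, 20, 20))
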