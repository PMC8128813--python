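"""Independent brute-force oracles shared by the test modules."""

import numpy as np

import habitatmap as hm
from habitatmap.core import HabitatError


def naive_stack(volume, mask, config):
    """Per-voxel reference texture engine: quantise, window, glcm, features.

    A straightforward loop over VOI voxels, independent of the vectorised
    sliding-window implementation.
    """
    extent = "volume" if config.window_masking == "volume" else "mask"
    levels = hm.quantize(volume, mask, config.n_levels, extent=extent)
    half = config.window // 2
    feats = np.zeros((9,) + volume.shape)
    valid = np.zeros(volume.shape, dtype=bool)
    for iz, iy, ix in zip(*np.nonzero(mask.voxels)):
        win = levels[iz, max(0, iy - half): iy + half + 1,
                     max(0, ix - half): ix + half + 1]
        try:
            p = hm.glcm(win, config.offsets, config.n_levels)
        except HabitatError:
            continue
        feats[:, iz, iy, ix] = hm.haralick_features(p)
        valid[iz, iy, ix] = True
    return feats, valid
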