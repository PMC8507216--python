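import numpy as np
import pytest

from strokerad.preprocessing import DiscretizedVOI, VOIMask


@pytest.fixture
def micro_slice_disc():
    """The 3x3 single-slice worked example with 3 gray levels."""
    sl = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]])
    lv = sl[:, :, None].astype(int)
    mask = VOIMask(np.ones_like(lv), (1.0, 1.0, 1.0))
    return DiscretizedVOI(lv, 3, (0.0, 1.0), mask)


def random_disc(rng, max_shape=(6, 6, 3), n_bins=4, mask_p=0.85):
    """Random small discretized VOI for oracle equivalence checks."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.where(mask, rng.integers(1, n_bins + 1, size=shape), 0)
    vmask = VOIMask(mask, (1.0, 1.0, 1.0))
    return DiscretizedVOI(levels, n_bins, (0.0, 1.0), vmask)
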