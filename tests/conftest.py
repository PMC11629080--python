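import numpy as np
import pytest

from petrad.grids import Modality, VolumeGrid


@pytest.fixture
def unit_grid():
    """Empty 40^3 volume at 1 mm spacing."""
    return VolumeGrid(np.zeros((40, 40, 40)), (1.0, 1.0, 1.0))


@pytest.fixture
def ball_mask():
    """Rasterized 10 mm ball at 1 mm spacing, with its brute-force oracle count."""
    n = 25
    c = (n - 1) / 2.0
    mask = np.zeros((n, n, n), dtype=bool)
    count = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if (i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2 <= 10.0**2:
                    mask[i, j, k] = True
                    count += 1
    return mask, count


def make_suv_volume(values, spacing=1.0):
    return VolumeGrid(np.asarray(values, dtype=float), (spacing,) * 3,
                      modality=Modality.PET_SUV)
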