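from __future__ import annotations

import numpy as np
import pytest

from xrh import new_volume


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def marker_volume():
    """Asymmetric fixture: a single bright voxel at (z=1, y=2, x=3) in a 4x5x6 grid.

    Shared across modules to pin the [z][y][x] index convention: any module
    that transposes axes moves the marker and fails.
    """
    data = np.zeros((4, 5, 6), dtype=np.float32)
    data[1, 2, 3] = 100.0
    return new_volume(data, voxel_size_um=8.48)
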