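import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dynomics.radiomics.discretize import QuantizedVoi


def random_qvoi(rng, shape=(5, 5, 3), ng=4, full_mask=False) -> QuantizedVoi:
    """Random quantized toy VOI for oracle-equivalence checks."""
    levels = rng.integers(1, ng + 1, size=shape)
    if full_mask:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = rng.random(shape) < 0.8
        if not mask.any():
            mask[0, 0, 0] = True
    lv = np.where(mask, levels, 0)
    return QuantizedVoi(lv, ng, mask, (1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def ball_mask():
    """Digitized ball of radius 8 voxels on a 19^3 grid."""
    n = 19
    c = n // 2
    xx, yy, zz = np.ogrid[:n, :n, :n]
    return (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= 8**2
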