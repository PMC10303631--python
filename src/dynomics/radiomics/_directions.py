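"""Direction offsets of the 3D 26-neighbourhood."""

from __future__ import annotations

import itertools

import numpy as np

#: 13 unique direction offsets (half of the 26-neighbourhood; the other half
#: are their negations).  First non-zero component positive.
UNIQUE_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)

#: all 26 neighbour offsets
ALL_NEIGHBOR_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

assert len(UNIQUE_DIRECTIONS) == 13
assert len(ALL_NEIGHBOR_OFFSETS) == 26


def shifted_views(a: np.ndarray, d: tuple[int, int, int]):
    """Views (center, neighbour) of ``a`` such that neighbour = center + d.

    Returns two equally-shaped views; element i of the first pairs with its
    d-offset neighbour in the second.
    """
    src, dst = [], []
    for k, s in zip(d, a.shape):
        if k == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif k > 0:
            src.append(slice(0, s - k))
            dst.append(slice(k, s))
        else:
            src.append(slice(-k, s))
            dst.append(slice(0, s + k))
    return a[tuple(src)], a[tuple(dst)]
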