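"""The 13 unique 3D lattice directions used by distance-1 texture matrices.

Opposite offsets describe the same voxel-pair geometry once matrices are
symmetrized, so one representative per +/- pair is kept.
"""

import numpy as np

DIRECTIONS_13 = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (1, -1, 0),
        (1, 0, 1),
        (1, 0, -1),
        (0, 1, 1),
        (0, 1, -1),
        (1, 1, 1),
        (1, 1, -1),
        (1, -1, 1),
        (-1, 1, 1),
    ],
    dtype=np.int64,
)

N_DIRECTIONS = 13


def offset_views(shape, offset):
    """Slice tuples (a, b) such that arr[a] and arr[b] are the two ends of
    every in-bounds voxel pair separated by ``offset``."""
    sl_a, sl_b = [], []
    for o in offset:
        o = int(o)
        if o >= 0:
            sl_a.append(slice(o, None))
            sl_b.append(slice(None, None if o == 0 else -o))
        else:
            sl_a.append(slice(None, o))
            sl_b.append(slice(-o, None))
    return tuple(sl_a), tuple(sl_b)
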