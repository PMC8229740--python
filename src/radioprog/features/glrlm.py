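"""Gray-level run-length matrix (GLRLM) features — 16 per image.

A run is a maximal collinear segment of voxels sharing a gray level; voxels
outside the ROI break runs. Runs are enumerated for the 13 unique 3D
directions by sorting ROI voxels on (line identifier, position along the
line) and cutting where the line, the position step, or the level changes —
no dense matrix is ever materialized. Features are computed per direction
and averaged.
"""

import numpy as np

from ._directions import DIRECTIONS_13, N_DIRECTIONS

GLRLM_FEATURE_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]


def glrlm_runs(level_grid):
    """Enumerate all runs in all 13 directions.

    Returns
    -------
    dir_idx, lvl, length : 1-D int arrays, one entry per run.
    """
    coords = np.argwhere(level_grid > 0)
    if coords.size == 0:
        raise ValueError("empty ROI")
    levels = level_grid[coords[:, 0], coords[:, 1], coords[:, 2]]
    span = int(max(level_grid.shape)) + 1
    dir_chunks, lvl_chunks, len_chunks = [], [], []
    for d in range(N_DIRECTIONS):
        dx, dy, dz = DIRECTIONS_13[d]
        step = int(dx * dx + dy * dy + dz * dz)  # t advances by |d|^2 per voxel
        t = coords[:, 0] * dx + coords[:, 1] * dy + coords[:, 2] * dz
        # voxels on one line share the (scaled, integer) projection of their
        # coordinates orthogonal to the direction; encode it as a single key
        k1 = coords[:, 0] * step - t * dx + 3 * span
        k2 = coords[:, 1] * step - t * dy + 3 * span
        k3 = coords[:, 2] * step - t * dz + 3 * span
        stride = 9 * span
        line = (k1 * stride + k2) * stride + k3
        order = np.lexsort((t, line))
        lt = t[order]
        ll = line[order]
        lv = levels[order]
        breaks = np.empty(lt.size, dtype=bool)
        breaks[0] = True
        breaks[1:] = (ll[1:] != ll[:-1]) | (lt[1:] != lt[:-1] + step) | (lv[1:] != lv[:-1])
        starts = np.flatnonzero(breaks)
        ends = np.append(starts[1:], lt.size)
        lengths = ends - starts
        dir_chunks.append(np.full(starts.size, d, dtype=np.int64))
        lvl_chunks.append(lv[starts])
        len_chunks.append(lengths)
    return (
        np.concatenate(dir_chunks),
        np.concatenate(lvl_chunks),
        np.concatenate(len_chunks),
    )


def glrlm_features(dir_idx, lvl, length, n_levels, n_voxels):
    """Compute the 16 GLRLM features from the run list, direction-averaged."""
    nd = N_DIRECTIONS
    ng = int(n_levels)
    i = lvl.astype(np.float64)
    j = length.astype(np.float64)

    def dsum(w):
        return np.bincount(dir_idx, weights=w, minlength=nd)

    nr = dsum(np.ones_like(j))
    if not np.all(nr > 0):
        raise ValueError("direction without runs in a non-empty ROI")

    sre = dsum(1.0 / (j * j)) / nr
    lre = dsum(j * j) / nr
    lglre = dsum(1.0 / (i * i)) / nr
    hglre = dsum(i * i) / nr
    srlgle = dsum(1.0 / (i * i * j * j)) / nr
    srhgle = dsum(i * i / (j * j)) / nr
    lrlgle = dsum(j * j / (i * i)) / nr
    lrhgle = dsum(i * i * j * j) / nr

    # gray-level marginal sum_j P(i,j), per direction
    ngp = ng + 1
    gmarg = np.bincount(dir_idx * ngp + lvl, minlength=nd * ngp).reshape(nd, ngp)
    gln = (gmarg.astype(np.float64) ** 2).sum(axis=1) / nr
    glnn = gln / nr
    # run-length marginal sum_i P(i,j)
    maxlen = int(length.max()) + 1
    rmarg = np.bincount(dir_idx * maxlen + length, minlength=nd * maxlen).reshape(nd, maxlen)
    rln = (rmarg.astype(np.float64) ** 2).sum(axis=1) / nr
    rlnn = rln / nr

    rp = nr / float(n_voxels)

    p = 1.0 / nr[dir_idx]  # each run carries probability 1/N_r
    mu_g = dsum(p * i)
    glv = dsum(p * (i - mu_g[dir_idx]) ** 2)
    mu_r = dsum(p * j)
    rv = dsum(p * (j - mu_r[dir_idx]) ** 2)

    # run entropy needs aggregated P(i,j) cells
    code = dir_idx * (ngp * maxlen) + lvl * maxlen + length
    uniq, counts = np.unique(code, return_counts=True)
    ud = uniq // (ngp * maxlen)
    pc = counts / nr[ud]
    re = np.bincount(ud, weights=-pc * np.log2(pc), minlength=nd)

    per_dir = {
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": glnn,
        "GrayLevelVariance": glv,
        "HighGrayLevelRunEmphasis": hglre,
        "LongRunEmphasis": lre,
        "LongRunHighGrayLevelEmphasis": lrhgle,
        "LongRunLowGrayLevelEmphasis": lrlgle,
        "LowGrayLevelRunEmphasis": lglre,
        "RunEntropy": re,
        "RunLengthNonUniformity": rln,
        "RunLengthNonUniformityNormalized": rlnn,
        "RunPercentage": rp,
        "RunVariance": rv,
        "ShortRunEmphasis": sre,
        "ShortRunHighGrayLevelEmphasis": srhgle,
        "ShortRunLowGrayLevelEmphasis": srlgle,
    }
    return {k: float(v.mean()) for k, v in per_dir.items()}


def glrlm_features_from_droi(droi):
    dir_idx, lvl, length = glrlm_runs(droi.level_grid)
    return glrlm_features(dir_idx, lvl, length, droi.n_levels, droi.levels.size)
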