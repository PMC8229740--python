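"""Gray-level co-occurrence matrix (GLCM) features — 24 per image.

Co-occurrences are counted at distance 1 along the 13 unique 3D directions,
symmetrized, normalized per direction; every feature is evaluated per
direction and then averaged over the directions that contain at least one
voxel pair.

Because 0.5 HU bins produce hundreds of gray levels, directional matrices are
kept as sparse (i, j, p) triplets tagged with a direction index, and feature
formulas are reduced with direction-grouped ``bincount`` sums. The MCC second
eigenvalue is obtained by deflated power iteration on the symmetrized
row-stochastic matrix, whose leading eigenpair (1, sqrt(p_x)) is known in
closed form.
"""

import numpy as np

from ._directions import DIRECTIONS_13, N_DIRECTIONS, offset_views

GLCM_FEATURE_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]


def glcm_sparse(level_grid, n_levels):
    """Build the 13 directional symmetric normalized GLCMs in sparse form.

    Parameters
    ----------
    level_grid : ndarray of int
        Gray levels 1..n_levels inside the ROI, 0 outside.
    n_levels : int
        N_g.

    Returns
    -------
    dir_idx, i, j, p : 1-D arrays
        Direction index (0..12), 1-based levels, and per-direction
        normalized probability of each nonzero cell.
    """
    ng = int(n_levels)
    dir_chunks, code_chunks = [], []
    for d in range(N_DIRECTIONS):
        sa, sb = offset_views(level_grid.shape, DIRECTIONS_13[d])
        a = level_grid[sa]
        b = level_grid[sb]
        m = (a > 0) & (b > 0)
        a = a[m]
        b = b[m]
        if a.size == 0:
            continue
        # symmetrization: count (a,b) and (b,a)
        code = np.concatenate([(a - 1) * ng + (b - 1), (b - 1) * ng + (a - 1)])
        code_chunks.append(code)
        dir_chunks.append(np.full(code.size, d, dtype=np.int64))
    if not code_chunks:
        return (np.empty(0, np.int64),) * 3 + (np.empty(0, np.float64),)
    codes = np.concatenate(code_chunks)
    dirs = np.concatenate(dir_chunks)
    full = dirs * (ng * ng) + codes
    uniq, counts = np.unique(full, return_counts=True)
    dir_idx = uniq // (ng * ng)
    cell = uniq % (ng * ng)
    i = cell // ng + 1
    j = cell % ng + 1
    totals = np.bincount(dir_idx, weights=counts, minlength=N_DIRECTIONS)
    p = counts / totals[dir_idx]
    return dir_idx, i, j, p.astype(np.float64)


def _mcc(dir_idx, i, j, p, px, valid, tol=1e-13, max_iter=2000):
    """sqrt of the second-largest eigenvalue of Q(i,j)=sum_k P(i,k)P(j,k)/(px(i)py(k)).

    Q is row-stochastic; it is similar to the symmetric S = B B^T with
    B(i,k) = P(i,k)/sqrt(px(i) py(k)), whose top eigenpair is
    (1, sqrt(px)). The second eigenvalue is found by power iteration on S
    with the top eigenvector deflated, batched over directions.
    """
    nd, ngp = px.shape
    u = np.sqrt(px)  # unit top eigenvector of S per direction
    b = p / np.sqrt(px[dir_idx, i] * px[dir_idx, j])
    key_i = dir_idx * ngp + i
    key_j = dir_idx * ngp + j
    size = nd * ngp

    rng = np.random.default_rng(12345)  # fixed: only breaks symmetry
    v = rng.standard_normal((nd, ngp))
    v[px == 0] = 0.0
    v -= (v * u).sum(axis=1, keepdims=True) * u
    norms = np.sqrt((v * v).sum(axis=1, keepdims=True))
    v /= np.where(norms > 0, norms, 1.0)

    lam_prev = np.zeros(nd)
    for it in range(max_iter):
        t = np.bincount(key_j, weights=b * v.ravel()[key_i], minlength=size)
        w = np.bincount(key_i, weights=b * t[key_j], minlength=size).reshape(nd, ngp)
        w -= (w * u).sum(axis=1, keepdims=True) * u
        lam = np.sqrt((w * w).sum(axis=1))
        nz = lam > 0
        v = np.where(nz[:, None], w / np.where(lam[:, None] > 0, lam[:, None], 1.0), v)
        if it % 8 == 7 and np.all(np.abs(lam - lam_prev) <= tol * np.maximum(lam, 1e-300)):
            break
        lam_prev = lam
    lam = np.clip(lam, 0.0, 1.0)
    out = np.sqrt(lam)
    # single-level directions are perfectly correlated by convention
    n_active = (px > 0).sum(axis=1)
    out[n_active <= 1] = 1.0
    out[~valid] = 0.0
    return out


def glcm_features(dir_idx, i, j, p, n_levels):
    """Compute the 24 GLCM features, averaged over non-empty directions."""
    ng = int(n_levels)
    ngp = ng + 1  # 1-based level columns, column 0 unused
    nd = N_DIRECTIONS
    valid = np.zeros(nd, dtype=bool)
    if dir_idx.size:
        valid[np.unique(dir_idx)] = True
    if not valid.any():
        raise ValueError("GLCM undefined: no voxel pairs in any direction")

    def dsum(w):
        return np.bincount(dir_idx, weights=w, minlength=nd)

    px = np.bincount(dir_idx * ngp + i, weights=p, minlength=nd * ngp).reshape(nd, ngp)
    lev = np.arange(ngp, dtype=np.float64)
    mu = (px * lev).sum(axis=1)  # = mu_x = mu_y (symmetric)
    mu_e = mu[dir_idx]

    diff = i - j
    adiff = np.abs(diff)
    ssum = i + j

    autoc = dsum(p * i * j)
    contrast = dsum(p * diff * diff)
    sumsq = dsum(p * (i - mu_e) ** 2)  # sigma_x^2, also SumSquares
    c = i + j - 2 * mu_e
    tend = dsum(p * c * c)
    shade = dsum(p * c * c * c)
    prom = dsum(p * c * c * c * c)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sumsq > 1e-12, (autoc - mu * mu) / np.where(sumsq > 0, sumsq, 1.0), 1.0)

    idf = dsum(p / (1.0 + adiff))
    idm = dsum(p / (1.0 + diff * diff))
    idmn = dsum(p / (1.0 + (diff / ng) ** 2))
    idn = dsum(p / (1.0 + adiff / ng))
    inv_var = dsum(np.where(adiff > 0, p / np.maximum(diff * diff, 1), 0.0))

    joint_energy = dsum(p * p)
    logp = np.log2(p, where=p > 0, out=np.zeros_like(p))
    joint_entropy = -dsum(p * logp)

    # difference and sum marginals (dense over k)
    pdiff = np.bincount(dir_idx * ngp + adiff, weights=p, minlength=nd * ngp).reshape(nd, ngp)
    da = (pdiff * lev).sum(axis=1)
    dvar = (pdiff * (lev[None, :] - da[:, None]) ** 2).sum(axis=1)
    lpd = np.log2(pdiff, where=pdiff > 0, out=np.zeros_like(pdiff))
    dentropy = -(pdiff * lpd).sum(axis=1)

    nsum = 2 * ngp
    psum = np.bincount(dir_idx * nsum + ssum, weights=p, minlength=nd * nsum).reshape(nd, nsum)
    ksum = np.arange(nsum, dtype=np.float64)
    sum_avg = (psum * ksum).sum(axis=1)
    lps = np.log2(psum, where=psum > 0, out=np.zeros_like(psum))
    sum_entropy = -(psum * lps).sum(axis=1)

    lpx = np.log2(px, where=px > 0, out=np.zeros_like(px))
    hx = -(px * lpx).sum(axis=1)
    lpx_e = lpx[dir_idx, i] + lpx[dir_idx, j]
    hxy1 = -dsum(p * lpx_e)
    hxy2 = 2.0 * hx  # closed form for symmetric GLCM: px == py
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = np.where(hx > 0, (joint_entropy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, 1.0))

    maxp = np.zeros(nd)
    np.maximum.at(maxp, dir_idx, p)

    mcc = _mcc(dir_idx, i, j, p, px, valid)

    per_dir = {
        "Autocorrelation": autoc,
        "ClusterProminence": prom,
        "ClusterShade": shade,
        "ClusterTendency": tend,
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": dentropy,
        "DifferenceVariance": dvar,
        "Id": idf,
        "Idm": idm,
        "Idmn": idmn,
        "Idn": idn,
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": joint_energy,
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": maxp,
        "SumAverage": sum_avg,
        "SumEntropy": sum_entropy,
        "SumSquares": sumsq,
    }
    return {k: float(v[valid].mean()) for k, v in per_dir.items()}


def glcm_features_from_droi(droi):
    """Convenience: sparse build + feature reduction from a DiscretizedRoi."""
    dir_idx, i, j, p = glcm_sparse(droi.level_grid, droi.n_levels)
    return glcm_features(dir_idx, i, j, p, droi.n_levels)
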