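"""Independent brute-force oracles used to validate the production code.

These deliberately share no code with the package: dense matrices, explicit
ray walking, direct ANOVA sums, pairwise AUC counting and a full
eigendecomposition for the MCC. They are slow and only run on tiny fixtures.
"""

import numpy as np

OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
]


def glcm_dense_oracle(level_grid, ng):
    """Per-direction dense symmetric normalized GLCMs by explicit pair loops."""
    nx, ny, nz = level_grid.shape
    mats = []
    for off in OFFSETS_13:
        p = np.zeros((ng, ng))
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    la = level_grid[x, y, z]
                    if la == 0:
                        continue
                    x2, y2, z2 = x + off[0], y + off[1], z + off[2]
                    if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                        continue
                    lb = level_grid[x2, y2, z2]
                    if lb == 0:
                        continue
                    p[la - 1, lb - 1] += 1
                    p[lb - 1, la - 1] += 1
        total = p.sum()
        mats.append(p / total if total > 0 else None)
    return mats


def glcm_features_oracle(level_grid, ng):
    """The 24 GLCM features from dense matrices, direction-averaged."""
    eps_free = {}
    mats = [m for m in glcm_dense_oracle(level_grid, ng) if m is not None]
    feats = {name: [] for name in [
        "Autocorrelation", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn",
        "Idn", "Imc1", "Imc2", "InverseVariance", "JointAverage",
        "JointEnergy", "JointEntropy", "MCC", "MaximumProbability",
        "SumAverage", "SumEntropy", "SumSquares"]}
    iv, jv = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1),
                         indexing="ij")
    for p in mats:
        px = p.sum(axis=1)
        mu = (np.arange(1, ng + 1) * px).sum()
        sigma2 = (px * (np.arange(1, ng + 1) - mu) ** 2).sum()
        nz = p > 0
        feats["Autocorrelation"].append((p * iv * jv).sum())
        feats["Contrast"].append((p * (iv - jv) ** 2).sum())
        feats["SumSquares"].append((p * (iv - mu) ** 2).sum())
        c = iv + jv - 2 * mu
        feats["ClusterTendency"].append((p * c**2).sum())
        feats["ClusterShade"].append((p * c**3).sum())
        feats["ClusterProminence"].append((p * c**4).sum())
        feats["Correlation"].append(
            ((p * iv * jv).sum() - mu * mu) / sigma2 if sigma2 > 1e-12 else 1.0
        )
        feats["JointAverage"].append(mu)
        feats["Id"].append((p / (1 + np.abs(iv - jv))).sum())
        feats["Idm"].append((p / (1 + (iv - jv) ** 2)).sum())
        feats["Idmn"].append((p / (1 + ((iv - jv) / ng) ** 2)).sum())
        feats["Idn"].append((p / (1 + np.abs(iv - jv) / ng)).sum())
        off_diag = iv != jv
        feats["InverseVariance"].append(
            (p[off_diag] / (iv - jv)[off_diag] ** 2).sum()
        )
        feats["JointEnergy"].append((p**2).sum())
        hxy = -(p[nz] * np.log2(p[nz])).sum()
        feats["JointEntropy"].append(hxy)
        feats["MaximumProbability"].append(p.max())
        # sum / difference distributions
        psum = np.zeros(2 * ng - 1)
        pdiff = np.zeros(ng)
        for i in range(ng):
            for j in range(ng):
                psum[i + j] += p[i, j]          # index = (i+1)+(j+1)-2
                pdiff[abs(i - j)] += p[i, j]
        ks = np.arange(2, 2 * ng + 1)
        feats["SumAverage"].append((ks * psum).sum())
        nzs = psum > 0
        feats["SumEntropy"].append(-(psum[nzs] * np.log2(psum[nzs])).sum())
        kd = np.arange(ng)
        da = (kd * pdiff).sum()
        feats["DifferenceAverage"].append(da)
        feats["DifferenceVariance"].append(((kd - da) ** 2 * pdiff).sum())
        nzd = pdiff > 0
        feats["DifferenceEntropy"].append(-(pdiff[nzd] * np.log2(pdiff[nzd])).sum())
        # information measures (symmetric: px == py)
        hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
        pxy = np.outer(px, px)
        both = nz
        hxy1 = -(p[both] * np.log2(pxy[both])).sum()
        hxy2 = -(pxy[pxy > 0] * np.log2(pxy[pxy > 0])).sum()
        feats["Imc1"].append((hxy - hxy1) / hx if hx > 0 else 0.0)
        feats["Imc2"].append(
            np.sqrt(np.clip(1 - np.exp(-2 * (hxy2 - hxy)), 0, 1))
        )
        feats["MCC"].append(mcc_eigh_oracle(p))
    return {k: float(np.mean(v)) for k, v in feats.items()}


def mcc_eigh_oracle(p):
    """MCC = sqrt(second-largest eigenvalue of Q) via dense eigh."""
    px = p.sum(axis=1)
    act = px > 0
    if act.sum() <= 1:
        return 1.0
    b = p[np.ix_(act, act)] / np.sqrt(np.outer(px[act], px[act]))
    ev = np.sort(np.linalg.eigvalsh(b @ b.T))
    return float(np.sqrt(max(ev[-2], 0.0)))


def glrlm_runs_oracle(level_grid):
    """Run lists per direction by walking every grid ray explicitly."""
    nx, ny, nz = level_grid.shape
    out = []
    for off in OFFSETS_13:
        runs = []
        # ray entry points: voxels whose predecessor is outside the grid
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    px_, py_, pz_ = x - off[0], y - off[1], z - off[2]
                    if 0 <= px_ < nx and 0 <= py_ < ny and 0 <= pz_ < nz:
                        continue
                    # walk the whole ray, split segments on level changes
                    cx, cy, cz = x, y, z
                    cur_level, cur_len = 0, 0
                    while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz:
                        lv = level_grid[cx, cy, cz]
                        if lv == cur_level:
                            cur_len += 1
                        else:
                            if cur_level > 0:
                                runs.append((cur_level, cur_len))
                            cur_level, cur_len = lv, 1
                        cx += off[0]
                        cy += off[1]
                        cz += off[2]
                    if cur_level > 0:
                        runs.append((cur_level, cur_len))
        out.append(runs)
    return out


def glrlm_features_oracle(level_grid, ng, n_vox):
    """The 16 GLRLM features from the oracle run lists, direction-averaged."""
    names = [
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ]
    acc = {k: [] for k in names}
    for runs in glrlm_runs_oracle(level_grid):
        nr = len(runs)
        i = np.array([r[0] for r in runs], dtype=float)
        j = np.array([r[1] for r in runs], dtype=float)
        p = np.zeros((int(i.max()) + 1, int(j.max()) + 1))
        for a, b in runs:
            p[a, b] += 1
        gmarg = p.sum(axis=1)
        rmarg = p.sum(axis=0)
        pr = p[p > 0] / nr
        acc["GrayLevelNonUniformity"].append((gmarg**2).sum() / nr)
        acc["GrayLevelNonUniformityNormalized"].append((gmarg**2).sum() / nr**2)
        acc["GrayLevelVariance"].append(((i - i.mean()) ** 2).mean())
        acc["HighGrayLevelRunEmphasis"].append((i**2).mean())
        acc["LongRunEmphasis"].append((j**2).mean())
        acc["LongRunHighGrayLevelEmphasis"].append((i**2 * j**2).mean())
        acc["LongRunLowGrayLevelEmphasis"].append((j**2 / i**2).mean())
        acc["LowGrayLevelRunEmphasis"].append((1 / i**2).mean())
        acc["RunEntropy"].append(-(pr * np.log2(pr)).sum())
        acc["RunLengthNonUniformity"].append((rmarg**2).sum() / nr)
        acc["RunLengthNonUniformityNormalized"].append((rmarg**2).sum() / nr**2)
        acc["RunPercentage"].append(nr / n_vox)
        acc["RunVariance"].append(((j - j.mean()) ** 2).mean())
        acc["ShortRunEmphasis"].append((1 / j**2).mean())
        acc["ShortRunHighGrayLevelEmphasis"].append((i**2 / j**2).mean())
        acc["ShortRunLowGrayLevelEmphasis"].append((1 / (i**2 * j**2)).mean())
    return {k: float(np.mean(v)) for k, v in acc.items()}


def icc_oracle(x):
    """One-way ANOVA variance components, written out longhand."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_between = sum(k * (x[s].mean() - grand) ** 2 for s in range(n))
    ss_within = sum(
        (x[s, m] - x[s].mean()) ** 2 for s in range(n) for m in range(k)
    )
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    return (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)


def auc_pair_oracle(scores, labels):
    """AUC by counting concordant positive-negative pairs (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def wilson_oracle(successes, n, z=1.959963984540054):
    """Closed-form Wilson score interval."""
    p = successes / n
    denom = 1 + z * z / n
    center = p + z * z / (2 * n)
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return (center - half) / denom, (center + half) / denom
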