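"""First-order (histogram) intensity statistics over an ROI — 18 features.

Entropy and Uniformity operate on the fixed-bin-width discretized levels;
everything else on raw intensities. Kurtosis is the non-excess moment ratio
m4/m2^2, so a normal distribution scores 3. The hot loop is compiled
(cohort studies evaluate these tens of thousands of times); quantiles use
one sort with numpy-style linear interpolation.
"""

import numpy as np
from numba import njit

FIRSTORDER_FEATURE_NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]

_LOG2 = 0.6931471805599453


@njit(cache=True)
def _first_order_kernel(x, levels, n_levels, voxel_volume):
    n = x.size
    xs = np.sort(x)
    # linear-interpolation quantiles (numpy default convention)
    q = np.empty(5)
    probs = (0.10, 0.25, 0.50, 0.75, 0.90)
    for t in range(5):
        pos = probs[t] * (n - 1)
        lo = int(pos)
        hi = lo + 1 if lo + 1 < n else n - 1
        q[t] = xs[lo] * (1.0 - (pos - lo)) + xs[hi] * (pos - lo)
    p10, p25, p50, p75, p90 = q[0], q[1], q[2], q[3], q[4]

    mean = 0.0
    energy = 0.0
    for t in range(n):
        mean += x[t]
        energy += x[t] * x[t]
    mean /= n
    m2 = 0.0
    m3 = 0.0
    m4 = 0.0
    mad = 0.0
    for t in range(n):
        d = x[t] - mean
        d2 = d * d
        m2 += d2
        m3 += d2 * d
        m4 += d2 * d2
        mad += abs(d)
    m2 /= n
    m3 /= n
    m4 /= n
    mad /= n

    r_sum = 0.0
    r_cnt = 0
    for t in range(n):
        if p10 <= x[t] <= p90:
            r_sum += x[t]
            r_cnt += 1
    rmad = 0.0
    if r_cnt > 0:
        r_mean = r_sum / r_cnt
        for t in range(n):
            if p10 <= x[t] <= p90:
                rmad += abs(x[t] - r_mean)
        rmad /= r_cnt

    counts = np.zeros(n_levels + 1, np.int64)
    for t in range(n):
        counts[levels[t]] += 1
    entropy = 0.0
    uniformity = 0.0
    for g in range(1, n_levels + 1):
        if counts[g] > 0:
            p = counts[g] / n
            entropy -= p * np.log(p) / _LOG2
            uniformity += p * p

    if m2 > 0.0:
        skewness = m3 / m2**1.5
        kurtosis = m4 / (m2 * m2)
    else:
        skewness = np.nan
        kurtosis = np.nan

    out = np.empty(18)
    out[0] = energy
    out[1] = voxel_volume * energy
    out[2] = entropy
    out[3] = xs[0]
    out[4] = p10
    out[5] = p90
    out[6] = xs[n - 1]
    out[7] = mean
    out[8] = p50
    out[9] = p75 - p25
    out[10] = xs[n - 1] - xs[0]
    out[11] = mad
    out[12] = rmad
    out[13] = np.sqrt(energy / n)
    out[14] = skewness
    out[15] = kurtosis
    out[16] = m2
    out[17] = uniformity
    return out


def first_order_features(values, levels, voxel_volume=1.0):
    """Compute the 18 first-order features.

    Parameters
    ----------
    values : ndarray
        Raw ROI intensities (>= 2 voxels).
    levels : ndarray of int
        Discretized gray levels of the same voxels (for Entropy/Uniformity).
    voxel_volume : float
        Physical volume of one voxel in mm^3 (TotalEnergy scaling).

    Returns
    -------
    dict name -> float. Skewness/Kurtosis are NaN for a zero-variance ROI
    (the caller logs and flags the patient).
    """
    x = np.ascontiguousarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("first-order features need at least 2 voxels")
    lv = np.ascontiguousarray(levels, dtype=np.int64)
    vals = _first_order_kernel(x, lv, int(lv.max()), float(voxel_volume))
    return dict(zip(FIRSTORDER_FEATURE_NAMES, vals.tolist()))
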