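"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's vectorised code paths: the
cross-correlation oracle is a direct double-loop evaluation of the
mean-subtracted, denominator-normalised formula, and the shift oracle is an
exhaustive integer-displacement normalized-correlation search.
"""

import itertools
import math

import numpy as np


def direct_cross_correlation(x, y):
    """All-lag cross-correlation by direct summation.

    Returns (lags, r) for d = -(N-1) .. (N-1) with
    r_d = sum_i (x_i - mx)(y_{i-d} - my) / sqrt(sum (x-mx)^2) / sqrt(sum (y-my)^2),
    the sum running over indices where both samples exist.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mx, my = x.mean(), y.mean()
    denom = math.sqrt(np.sum((x - mx) ** 2)) * math.sqrt(np.sum((y - my) ** 2))
    lags = np.arange(-(n - 1), n)
    r = np.zeros(lags.size)
    for k, d in enumerate(lags):
        s = 0.0
        for i in range(n):
            j = i - d
            if 0 <= j < n:
                s += (x[i] - mx) * (y[j] - my)
        r[k] = s / denom
    return lags, r


def exhaustive_integer_shift(frame_a, frame_b, center, block_shape, radius):
    """Best integer displacement of a block by exhaustive NCC search.

    Cuts a block around ``center`` in ``frame_a`` and correlates it against
    every integer shift within ``radius`` in ``frame_b``; ties go to the
    smallest displacement magnitude, then lexicographic (dr, dc).
    """
    bh, bw = block_shape
    hb, wb = bh // 2, bw // 2
    r0, c0 = center
    block = frame_a[r0 - hb : r0 + hb + 1, c0 - wb : c0 + wb + 1].astype(float)
    bz = block - block.mean()
    bn = math.sqrt(np.sum(bz**2))
    best = None
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = r0 + dr, c0 + dc
            cand = frame_b[r - hb : r + hb + 1, c - wb : c + wb + 1].astype(float)
            cz = cand - cand.mean()
            cn = math.sqrt(np.sum(cz**2))
            ncc = float(np.sum(bz * cz) / (bn * cn)) if bn * cn > 0 else 0.0
            key = (-ncc, dr * dr + dc * dc, dr, dc)
            if best is None or key < best[0]:
                best = (key, (dr, dc), ncc)
    return best[1], best[2]


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p-value by exhaustive enumeration (small, tie-free)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in a)
    n = len(a)
    all_ranks = range(1, len(pooled) + 1)
    stats = [sum(comb) for comb in itertools.combinations(all_ranks, n)]
    mean_w = (n * (len(pooled) + 1)) / 2.0
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in stats if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(stats)


def descriptive_stats(values):
    """The seven lag statistics by explicit formula evaluation."""
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = v.sum() / n
    m2 = np.sum((v - mean) ** 2) / n
    m3 = np.sum((v - mean) ** 3) / n
    m4 = np.sum((v - mean) ** 4) / n
    sd = math.sqrt(np.sum((v - mean) ** 2) / (n - 1)) if n > 1 else 0.0
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    return {
        "max": float(v.max()),
        "min": float(v.min()),
        "mean": float(mean),
        "median": float(np.median(v)),
        "stdev": float(sd),
        "skewness": float(skew),
        "kurtosis": float(kurt),
    }
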