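"""Independent brute-force oracles for texture matrices and statistics.

Everything here is written as plain nested loops over voxels, kept
deliberately naive and separate from the package's vectorized
implementations, for use on tiny ROIs only.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def _in_bounds(idx, shape) -> bool:
    return all(0 <= i < s for i, s in zip(idx, shape))


def oracle_glcm(levels: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset."""
    P = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                nb = (x + offset[0], y + offset[1], z + offset[2])
                if not _in_bounds(nb, shape):
                    continue
                j = levels[nb]
                if j == 0:
                    continue
                P[i - 1, j - 1] += 1
                P[j - 1, i - 1] += 1
    return P


def oracle_runs(levels: np.ndarray, direction) -> Counter:
    """Counter of (gray level, run length) over maximal runs."""
    shape = levels.shape
    runs: Counter = Counter()
    d = tuple(direction)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                prev = (x - d[0], y - d[1], z - d[2])
                if _in_bounds(prev, shape):
                    continue  # not a line start
                # walk the whole line from this start voxel
                cur = (x, y, z)
                line = []
                while _in_bounds(cur, shape):
                    line.append(levels[cur])
                    cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                k = 0
                while k < len(line):
                    g = line[k]
                    length = 1
                    while k + length < len(line) and line[k + length] == g:
                        length += 1
                    if g > 0:
                        runs[(int(g), length)] += 1
                    k += length
    return runs


def oracle_zones(levels: np.ndarray, ng: int) -> Counter:
    """Counter of (gray level, zone size) with 26-connectivity flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: Counter = Counter()
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if seen[x, y, z] or levels[x, y, z] == 0:
                    continue
                g = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cur = stack.pop()
                    size += 1
                    for off in offsets:
                        nb = tuple(c + o for c, o in zip(cur, off))
                        if _in_bounds(nb, shape) and not seen[nb] and levels[nb] == g:
                            seen[nb] = True
                            stack.append(nb)
                zones[(int(g), size)] += 1
    return zones


def oracle_dependence(levels: np.ndarray, alpha: int = 0) -> Counter:
    """Counter of (gray level, dependence size); size = 1 + #neighbors
    within alpha levels (26-neighborhood)."""
    shape = levels.shape
    deps: Counter = Counter()
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                count = 0
                for off in offsets:
                    nb = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(nb, shape) and levels[nb] > 0 and abs(int(levels[nb]) - int(g)) <= alpha:
                        count += 1
                deps[(int(g), count + 1)] += 1
    return deps


def oracle_ngtdm(levels: np.ndarray, ng: int):
    """(n_i, s_i) per gray level from explicit neighbor-mean loops."""
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                n_i[g - 1] += 1
                nbs = []
                for off in offsets:
                    nb = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(nb, shape) and levels[nb] > 0:
                        nbs.append(levels[nb])
                if nbs:
                    s_i[g - 1] += abs(g - sum(nbs) / len(nbs))
    return n_i, s_i


def oracle_firstorder(values: np.ndarray, bin_width: float = 25.0) -> dict:
    """Naive reimplementations of the first-order statistics."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    p10, p90 = np.percentile(v, 10), np.percentile(v, 90)
    p25, p75 = np.percentile(v, 25), np.percentile(v, 75)
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    counts = Counter(math.floor((x - v[0]) / bin_width) for x in v)
    probs = [c / n for c in counts.values()]
    m2 = var
    out = {
        "Energy": sum(x * x for x in v),
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": v[0],
        "Maximum": v[-1],
        "Mean": mean,
        "Median": float(np.median(v)),
        "Range": v[-1] - v[0],
        "InterquartileRange": float(p75 - p25),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(x - rmean) for x in robust) / len(robust),
        "RootMeanSquared": math.sqrt(sum(x * x for x in v) / n),
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
        "Skewness": (sum((x - mean) ** 3 for x in v) / n) / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": (sum((x - mean) ** 4 for x in v) / n) / m2**2 if m2 > 0 else 0.0,
    }
    return out


def oracle_windowed_abs_sum(arr: np.ndarray) -> np.ndarray:
    """3x3 sum of |values| with edge replication (LEM oracle)."""
    h, w = arr.shape
    out = np.zeros_like(arr, dtype=float)
    for i in range(h):
        for j in range(w):
            s = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    s += abs(arr[ii, jj])
            out[i, j] = s
    return out


def oracle_mld(arr: np.ndarray) -> np.ndarray:
    """Brute-force 3x3 directional-sum MLD with edge replication."""
    h, w = arr.shape
    dirs = [
        [(0, -1), (0, 0), (0, 1)],
        [(-1, 0), (0, 0), (1, 0)],
        [(-1, -1), (0, 0), (1, 1)],
        [(-1, 1), (0, 0), (1, -1)],
    ]
    out = np.zeros_like(arr, dtype=float)
    for i in range(h):
        for j in range(w):
            best = 0.0
            for d in dirs:
                s = 0.0
                for di, dj in d:
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    s += arr[ii, jj]
                best = max(best, abs(3.0 * arr[i, j] - s))
            out[i, j] = best
    return out
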