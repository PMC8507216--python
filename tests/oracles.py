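"""Independent brute-force oracles: nested-loop pair/run/zone enumeration.

Deliberately slow and simple, structured nothing like the vectorized
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

STEPS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def glcm_bruteforce(levels: np.ndarray, angle: int, offset: int, n_bins: int):
    """Symmetrized normalized co-occurrence counts by explicit voxel loops."""
    di, dj = STEPS[angle]
    di, dj = di * offset, dj * offset
    nx, ny, nz = levels.shape
    counts = np.zeros((n_bins, n_bins))
    for z in range(nz):
        for i in range(nx):
            for j in range(ny):
                a = levels[i, j, z]
                if a == 0:
                    continue
                i2, j2 = i + di, j + dj
                if 0 <= i2 < nx and 0 <= j2 < ny:
                    b = levels[i2, j2, z]
                    if b > 0:
                        counts[a - 1, b - 1] += 1
                        counts[b - 1, a - 1] += 1
    total = counts.sum()
    if total == 0:
        return None, 0
    return counts / total, int(total)


def rlm_bruteforce(levels: np.ndarray, angle: int, step: int, n_bins: int):
    """Run counts on sampled rays, walking each ray start explicitly."""
    di, dj = STEPS[angle]
    nx, ny, nz = levels.shape
    runs = []  # (level, length)
    for z in range(nz):
        for i0 in range(nx):
            for j0 in range(ny):
                # start only where the predecessor sample is off-grid
                ip, jp = i0 - di * step, j0 - dj * step
                if 0 <= ip < nx and 0 <= jp < ny:
                    continue
                seq = []
                i, j = i0, j0
                while 0 <= i < nx and 0 <= j < ny:
                    seq.append(levels[i, j, z])
                    i, j = i + di * step, j + dj * step
                cur, cur_len = None, 0
                for v in seq + [None]:
                    if v == cur and v is not None:
                        cur_len += 1
                    else:
                        if cur is not None and cur > 0:
                            runs.append((cur, cur_len))
                        cur, cur_len = v, 1
    if not runs:
        return None, 0
    max_r = max(r for _, r in runs)
    R = np.zeros((n_bins, max_r))
    for g, r in runs:
        R[g - 1, r - 1] += 1
    return R, len(runs)


def glszm_bruteforce(levels: np.ndarray, n_bins: int):
    """26-connected zones via flood fill."""
    nx, ny, nz = levels.shape
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []  # (level, size)
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                stack, size = [(x, y, z)], 0
                seen[x, y, z] = True
                while stack:
                    i, j, k = stack.pop()
                    size += 1
                    for a, b, c in offsets:
                        i2, j2, k2 = i + a, j + b, k + c
                        if (
                            0 <= i2 < nx
                            and 0 <= j2 < ny
                            and 0 <= k2 < nz
                            and not seen[i2, j2, k2]
                            and levels[i2, j2, k2] == g
                        ):
                            seen[i2, j2, k2] = True
                            stack.append((i2, j2, k2))
                zones.append((int(g), size))
    max_s = max(s for _, s in zones)
    Z = np.zeros((n_bins, max_s))
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z, len(zones), int((levels > 0).sum())


def surface_area_bruteforce(mask: np.ndarray, spacing) -> float:
    """Count exposed faces voxel by voxel."""
    sx, sy, sz = spacing
    areas = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    nx, ny, nz = mask.shape
    total = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                for axis, (a, b, c) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
                    for sgn in (-1, 1):
                        i2, j2, k2 = i + sgn * a, j + sgn * b, k + sgn * c
                        exposed = (
                            not (0 <= i2 < nx and 0 <= j2 < ny and 0 <= k2 < nz)
                            or not mask[i2, j2, k2]
                        )
                        if exposed:
                            total += areas[axis]
    return total


def max_diameter_bruteforce(mask: np.ndarray, spacing) -> float:
    pts = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            best = max(best, d)
    return best


def auc_paircount(scores, labels) -> float:
    """Exhaustive concordant-pair AUC with ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def mcnemar_exact_bruteforce(b: int, c: int) -> float:
    """Two-sided exact binomial by enumeration of all outcomes."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, t) for t in range(0, k + 1)) / 2.0**n
    return min(1.0, 2.0 * tail)


def glcm_features_bruteforce(p: np.ndarray) -> dict:
    """Co-occurrence statistics via explicit double loops."""
    n = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    mu_y = sum((j + 1) * p[i, j] for i in range(n) for j in range(n))
    var_x = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_y = sum((j + 1 - mu_y) ** 2 * p[i, j] for i in range(n) for j in range(n))
    out = {
        "Energy": sum(p[i, j] ** 2 for i in range(n) for j in range(n)),
        "Entropy": -sum(
            p[i, j] * math.log2(p[i, j])
            for i in range(n)
            for j in range(n)
            if p[i, j] > 0
        ),
        "Inertia": sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)),
        "InverseDifferenceMoment": sum(
            p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)
        ),
        "ClusterShade": sum(
            (i + j + 2 - mu_x - mu_y) ** 3 * p[i, j] for i in range(n) for j in range(n)
        ),
        "ClusterProminence": sum(
            (i + j + 2 - mu_x - mu_y) ** 4 * p[i, j] for i in range(n) for j in range(n)
        ),
    }
    sx, sy = math.sqrt(var_x), math.sqrt(var_y)
    if sx > 0 and sy > 0:
        out["Correlation"] = (
            sum(
                (i + 1 - mu_x) * (j + 1 - mu_y) * p[i, j]
                for i in range(n)
                for j in range(n)
            )
            / (sx * sy)
        )
        out["HaralickCorrelation"] = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n))
            - mu_x * mu_y
        ) / (sx * sy)
    else:
        out["Correlation"] = 0.0
        out["HaralickCorrelation"] = 0.0
    return out


def rlm_features_bruteforce(R: np.ndarray, Nr: int) -> dict:
    n_g, n_r = R.shape
    acc = {
        "ShortRunEmphasis": 0.0,
        "LongRunEmphasis": 0.0,
        "LowGreyLevelRunEmphasis": 0.0,
        "HighGreyLevelRunEmphasis": 0.0,
        "ShortRunLowGreyLevelEmphasis": 0.0,
        "ShortRunHighGreyLevelEmphasis": 0.0,
        "LongRunLowGreyLevelEmphasis": 0.0,
        "LongRunHighGreyLevelEmphasis": 0.0,
    }
    for gi in range(n_g):
        g = gi + 1
        for ri in range(n_r):
            r = ri + 1
            v = R[gi, ri]
            acc["ShortRunEmphasis"] += v / r**2
            acc["LongRunEmphasis"] += v * r**2
            acc["LowGreyLevelRunEmphasis"] += v / g**2
            acc["HighGreyLevelRunEmphasis"] += v * g**2
            acc["ShortRunLowGreyLevelEmphasis"] += v / (g**2 * r**2)
            acc["ShortRunHighGreyLevelEmphasis"] += v * g**2 / r**2
            acc["LongRunLowGreyLevelEmphasis"] += v * r**2 / g**2
            acc["LongRunHighGreyLevelEmphasis"] += v * g**2 * r**2
    out = {k: v / Nr for k, v in acc.items()}
    out["GreyLevelNonuniformity"] = sum(R[gi, :].sum() ** 2 for gi in range(n_g)) / Nr
    out["RunLengthNonuniformity"] = sum(R[:, ri].sum() ** 2 for ri in range(n_r)) / Nr
    return out


def glszm_features_bruteforce(Z: np.ndarray, Nz: int, n_vox: int) -> dict:
    out = rlm_features_bruteforce(Z, Nz)
    renames = {
        "ShortRunEmphasis": "SmallZoneEmphasis",
        "LongRunEmphasis": "LargeZoneEmphasis",
        "LowGreyLevelRunEmphasis": "LowGreyLevelZoneEmphasis",
        "HighGreyLevelRunEmphasis": "HighGreyLevelZoneEmphasis",
        "ShortRunLowGreyLevelEmphasis": "SmallZoneLowGreyLevelEmphasis",
        "ShortRunHighGreyLevelEmphasis": "SmallZoneHighGreyLevelEmphasis",
        "LongRunLowGreyLevelEmphasis": "LargeZoneLowGreyLevelEmphasis",
        "LongRunHighGreyLevelEmphasis": "LargeZoneHighGreyLevelEmphasis",
        "RunLengthNonuniformity": "ZoneSizeNonuniformity",
        "GreyLevelNonuniformity": "GreyLevelNonuniformity",
    }
    res = {renames[k]: v for k, v in out.items()}
    res["ZonePercentage"] = Nz / n_vox
    return res


def histogram_bruteforce(values) -> dict:
    """First-order statistics by sorting and explicit sums."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    mean = sum(xs) / n
    med = (xs[(n - 1) // 2] + xs[n // 2]) / 2.0
    var = sum((v - mean) ** 2 for v in xs) / n

    def pct(p):
        return xs[max(1, math.ceil(p / 100.0 * n)) - 1]

    return {
        "Minimum": xs[0],
        "Maximum": xs[-1],
        "Mean": mean,
        "Median": med,
        "Variance": var,
        "Percentile20": pct(20),
        "InterquartileRange": pct(75) - pct(25),
        "TotalExcessOverMedian": sum(max(v - med, 0.0) for v in xs),
        "NVoxels": float(n),
    }
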