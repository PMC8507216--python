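"""First-order (histogram) statistics of the in-mask intensities.

42 values: 21 summary statistics and 21 nearest-rank percentiles
{1, 5, 10, ..., 95, 99}. The nearest-rank percentile p is the
ceil(p/100 * n)-th order statistic, matching the inverse-CDF definition
P(a) = p%.
"""

from __future__ import annotations

import math

import numpy as np

PERCENTILE_LEVELS = (1,) + tuple(range(5, 100, 5)) + (99,)

SUMMARY_NAMES = (
    "Minimum",
    "Maximum",
    "Range",
    "Mean",
    "Median",
    "Mode",
    "StdDev",
    "Variance",
    "MeanAbsoluteDeviation",
    "RootMeanSquare",
    "Energy",
    "Entropy",
    "Uniformity",
    "Skewness",
    "Kurtosis",
    "CoefficientOfVariation",
    "InterquartileRange",
    "RobustMeanAbsoluteDeviation",
    "Percentile10_90Mean",
    "TotalExcessOverMedian",
    "NVoxels",
)

HISTOGRAM_NAMES = SUMMARY_NAMES + tuple(f"Percentile{p}" for p in PERCENTILE_LEVELS)


def nearest_rank_percentile(sorted_values: np.ndarray, p: float) -> float:
    """ceil(p/100 * n)-th order statistic of an ascending array."""
    n = sorted_values.size
    k = max(1, math.ceil(p / 100.0 * n))
    return float(sorted_values[k - 1])


def histogram_features(volume, mask, n_bins: int = 64) -> dict[str, float]:
    """All 42 first-order statistics of the in-mask intensities.

    ``n_bins`` controls the equal-width histogram (spanning the observed
    value range) behind Mode, Entropy and Uniformity. Moments use the
    population convention; Kurtosis is the Pearson (non-excess) form and a
    constant region reports Skewness 0, Kurtosis 0, Entropy 0, Uniformity 1.
    """
    x = np.asarray(volume.voxels)[np.asarray(mask.voxels) > 0].astype(float)
    if x.size == 0:
        raise ValueError("empty mask")
    n = x.size
    xs = np.sort(x)
    mean = float(x.mean())
    median = float(np.median(x))
    var = float(x.var(ddof=0))
    sd = math.sqrt(var)

    if xs[0] == xs[-1]:
        probs = np.array([1.0])
        mode = float(xs[0])
    else:
        counts, edges = np.histogram(x, bins=n_bins)
        probs = counts / n
        mode = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    nz = probs[probs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((nz**2).sum())

    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0

    p10 = nearest_rank_percentile(xs, 10)
    p90 = nearest_rank_percentile(xs, 90)
    mid = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
    mid_mean = float(mid.mean()) if mid.size else mean

    out = {
        "Minimum": float(xs[0]),
        "Maximum": float(xs[-1]),
        "Range": float(xs[-1] - xs[0]),
        "Mean": mean,
        "Median": median,
        "Mode": mode,
        "StdDev": sd,
        "Variance": var,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RootMeanSquare": float(math.sqrt((x**2).mean())),
        "Energy": float((x**2).sum()),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "Skewness": skew,
        "Kurtosis": kurt,
        "CoefficientOfVariation": sd / mean if mean != 0 else 0.0,
        "InterquartileRange": nearest_rank_percentile(xs, 75) - nearest_rank_percentile(xs, 25),
        "RobustMeanAbsoluteDeviation": robust_mad,
        "Percentile10_90Mean": mid_mean,
        "TotalExcessOverMedian": float(np.maximum(x - median, 0.0).sum()),
        "NVoxels": float(n),
    }
    for p in PERCENTILE_LEVELS:
        out[f"Percentile{p}"] = nearest_rank_percentile(xs, p)
    return out
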