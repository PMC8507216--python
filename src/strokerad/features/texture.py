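"""Feature formulas on the texture matrices, plus Haralick statistics."""

from __future__ import annotations

import numpy as np

from ..preprocessing import DiscretizedVOI
from .matrices import (
    ANGLES,
    CooccurrenceMatrix,
    RunLengthMatrix,
    SizeZoneMatrix,
    UndefinedMatrixError,
    cooccurrence_matrix,
)

GLCM_BASES = (
    "Energy",
    "Entropy",
    "Inertia",
    "Correlation",
    "InverseDifferenceMoment",
    "ClusterShade",
    "ClusterProminence",
    "HaralickCorrelation",
)

RLM_BASES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GreyLevelNonuniformity",
    "RunLengthNonuniformity",
    "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis",
    "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis",
    "LongRunLowGreyLevelEmphasis",
    "LongRunHighGreyLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallZoneEmphasis",
    "LargeZoneEmphasis",
    "GreyLevelNonuniformity",
    "ZoneSizeNonuniformity",
    "ZonePercentage",
    "LowGreyLevelZoneEmphasis",
    "HighGreyLevelZoneEmphasis",
    "SmallZoneLowGreyLevelEmphasis",
    "SmallZoneHighGreyLevelEmphasis",
    "LargeZoneLowGreyLevelEmphasis",
    "LargeZoneHighGreyLevelEmphasis",
)

HARALICK_NAMES = (
    "AngularSecondMoment",
    "Contrast",
    "Correlation",
    "SumOfSquaresVariance",
    "InverseDifferenceMoment",
    "SumAverage",
    "SumEntropy",
    "SumVariance",
    "DifferenceEntropy",
    "DifferenceVariance",
)


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits with 0*log(0) := 0."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The eight co-occurrence statistics used on the per-(angle, offset) grid.

    Zero marginal variance makes the two correlations undefined; they are
    reported as 0 (degenerate texture carries no correlation signal).
    """
    p = m.p
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    mu_y = mu_x  # symmetric matrix
    var_x = float(((i - mu_x) ** 2 * px).sum())
    sig = np.sqrt(var_x)
    out = {
        "Energy": float((p**2).sum()),
        "Entropy": _entropy2(p),
        "Inertia": float(((ii - jj) ** 2 * p).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
    }
    if sig > 0:
        out["Correlation"] = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sig * sig))
        out["HaralickCorrelation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig * sig))
    else:
        out["Correlation"] = 0.0
        out["HaralickCorrelation"] = 0.0
    return {k: out[k] for k in GLCM_BASES}


def rlm_features(m: RunLengthMatrix) -> dict[str, float]:
    R, Nr = m.R, m.Nr
    n_g, n_r = R.shape
    g = np.arange(1, n_g + 1)[:, None].astype(float)
    r = np.arange(1, n_r + 1)[None, :].astype(float)
    rg = R.sum(axis=1)  # per level
    rr = R.sum(axis=0)  # per length
    return {
        "ShortRunEmphasis": float((R / r**2).sum() / Nr),
        "LongRunEmphasis": float((R * r**2).sum() / Nr),
        "GreyLevelNonuniformity": float((rg**2).sum() / Nr),
        "RunLengthNonuniformity": float((rr**2).sum() / Nr),
        "LowGreyLevelRunEmphasis": float((R / g**2).sum() / Nr),
        "HighGreyLevelRunEmphasis": float((R * g**2).sum() / Nr),
        "ShortRunLowGreyLevelEmphasis": float((R / (g**2 * r**2)).sum() / Nr),
        "ShortRunHighGreyLevelEmphasis": float((R * g**2 / r**2).sum() / Nr),
        "LongRunLowGreyLevelEmphasis": float((R * r**2 / g**2).sum() / Nr),
        "LongRunHighGreyLevelEmphasis": float((R * g**2 * r**2).sum() / Nr),
    }


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    """Run-length formula pattern applied to (level, zone size) counts."""
    Z, Nz = m.Z, m.Nz
    n_g, n_s = Z.shape
    g = np.arange(1, n_g + 1)[:, None].astype(float)
    s = np.arange(1, n_s + 1)[None, :].astype(float)
    zg = Z.sum(axis=1)
    zs = Z.sum(axis=0)
    return {
        "SmallZoneEmphasis": float((Z / s**2).sum() / Nz),
        "LargeZoneEmphasis": float((Z * s**2).sum() / Nz),
        "GreyLevelNonuniformity": float((zg**2).sum() / Nz),
        "ZoneSizeNonuniformity": float((zs**2).sum() / Nz),
        "ZonePercentage": float(Nz / m.n_voxels),
        "LowGreyLevelZoneEmphasis": float((Z / g**2).sum() / Nz),
        "HighGreyLevelZoneEmphasis": float((Z * g**2).sum() / Nz),
        "SmallZoneLowGreyLevelEmphasis": float((Z / (g**2 * s**2)).sum() / Nz),
        "SmallZoneHighGreyLevelEmphasis": float((Z * g**2 / s**2).sum() / Nz),
        "LargeZoneLowGreyLevelEmphasis": float((Z * s**2 / g**2).sum() / Nz),
        "LargeZoneHighGreyLevelEmphasis": float((Z * g**2 * s**2).sum() / Nz),
    }


def _haralick_single(m: CooccurrenceMatrix) -> dict[str, float]:
    p = m.p
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    sig = np.sqrt(var)
    # p_{x+y}(k), k = 2..2n ; p_{x-y}(k), k = 0..n-1
    sums = np.zeros(2 * n + 1)
    np.add.at(sums, (ii + jj).ravel(), p.ravel())
    diffs = np.zeros(n)
    np.add.at(diffs, np.abs(ii - jj).ravel(), p.ravel())
    ks = np.arange(2 * n + 1).astype(float)
    kd = np.arange(n).astype(float)
    sum_avg = float((ks * sums).sum())
    diff_avg = float((kd * diffs).sum())
    corr = float((((ii - mu) * (jj - mu) * p).sum()) / var) if var > 0 else 0.0
    return {
        "AngularSecondMoment": float((p**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "SumOfSquaresVariance": float(((ii - mu) ** 2 * p).sum()),
        "InverseDifferenceMoment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "SumAverage": sum_avg,
        "SumEntropy": _entropy2(sums),
        "SumVariance": float(((ks - sum_avg) ** 2 * sums).sum()),
        "DifferenceEntropy": _entropy2(diffs),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * diffs).sum()),
    }


def haralick_features(disc: DiscretizedVOI) -> dict[str, float]:
    """Ten classic Haralick statistics at offset 1, averaged over 4 angles."""
    per_angle = []
    for angle in ANGLES:
        try:
            per_angle.append(_haralick_single(cooccurrence_matrix(disc, angle, 1)))
        except UndefinedMatrixError:
            continue
    if not per_angle:
        raise UndefinedMatrixError("co-occurrence undefined at every angle")
    return {
        name: float(np.mean([d[name] for d in per_angle])) for name in HARALICK_NAMES
    }


def aggregate_directions(values) -> tuple[float, float]:
    """AllDirection aggregation: arithmetic mean and population SD (div. 4)."""
    v = np.asarray(values, dtype=float)
    if v.size != 4 or not np.all(np.isfinite(v)):
        raise UndefinedMatrixError("AllDirection aggregation needs 4 finite per-angle values")
    return float(v.mean()), float(v.std(ddof=0))
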