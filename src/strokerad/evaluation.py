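"""Discrimination, comparison, calibration-free utility and reliability.

* DeLong nonparametric AUC variance/covariance (placement values with
  midranks), Wald CIs, and the paired two-ROC z-test,
* Youden-index operating points,
* McNemar paired comparison of classification correctness,
* decision-curve analysis with extraction of the beneficial threshold range,
* intraclass correlation coefficients (two-way ANOVA forms),
* Spearman feature-covariate correlation screens.

The positive class is the early (<= 4.5 h) stratum, coded 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """AUC and per-subject placement values (ties count one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    # V10[i] = fraction of negatives below positive i (ties half)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    return auc, v10, v01


@dataclass
class ROCResult:
    auc: float
    se: float
    ci: tuple[float, float]
    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Sens/spec at every classification rule score >= t, t over unique scores."""
    thr = np.unique(scores)[::-1]
    pos = labels == 1
    sens = np.array([(scores[pos] >= t).mean() for t in thr])
    spec = np.array([(scores[~pos] < t).mean() for t in thr])
    return thr, sens, spec


def auc_delong(scores, labels) -> ROCResult:
    """Mann-Whitney AUC with DeLong standard error and truncated Wald 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc, v10, v01 = _placements(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    thr, sens, spec = _roc_points(s, y)
    return ROCResult(auc, se, ci, thr, sens, spec)


def delong_variance(scores, labels) -> float:
    r = auc_delong(scores, labels)
    return r.se**2


@dataclass
class ComparisonResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    degenerate: bool = False


def delong_compare(scores_a, scores_b, labels) -> ComparisonResult:
    """Two-sided paired DeLong z-test on the AUC difference."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("paired scores must cover the same subjects")
    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return ComparisonResult(auc_a, auc_b, 0.0, 1.0, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult(auc_a, auc_b, float(z), p)


# ---------------------------------------------------------------------------
# Operating point
# ---------------------------------------------------------------------------


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_point(roc: ROCResult) -> OperatingPoint:
    """Maximize J = sens + spec - 1; ties -> higher sensitivity, then lower
    threshold."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = None
    for k in range(len(roc.thresholds)):
        cand = (j[k], roc.sensitivity[k], -roc.thresholds[k])
        if best is None or cand > best[0]:
            best = (cand, k)
    k = best[1]
    return OperatingPoint(
        float(roc.thresholds[k]),
        float(roc.sensitivity[k]),
        float(roc.specificity[k]),
        float(j[k]),
    )


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


@dataclass
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    p: float
    method: str


def mcnemar_compare(pred_a, pred_b, labels, exact_limit: int = 25) -> McNemarResult:
    """Paired McNemar test on classification correctness.

    Exact two-sided binomial (doubled smaller tail, capped at 1) when
    b + c < exact_limit, else chi-square with continuity correction.
    """
    pa = np.asarray(pred_a).astype(int)
    pb = np.asarray(pred_b).astype(int)
    y = np.asarray(labels).astype(int)
    ca, cb = pa == y, pb == y
    b = int((ca & ~cb).sum())
    c = int((~ca & cb).sum())
    n = b + c
    if n == 0:
        return McNemarResult(b, c, 1.0, "exact")
    if n < exact_limit:
        k = min(b, c)
        p = min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))
        return McNemarResult(b, c, float(p), "exact")
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    return McNemarResult(b, c, float(stats.chi2.sf(chi2, 1)), "chi2")


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------


@dataclass
class DCAResult:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    beneficial_range: tuple[float, float] | None


def decision_curve(probs, labels, grid_step: float = 0.01) -> DCAResult:
    """Net benefit across threshold probabilities.

    NB_model(pt) = TP/n - (FP/n) * pt/(1-pt), classifying at prob >= pt;
    NB_all(pt) = pi - (1-pi) * pt/(1-pt); NB_none = 0. The beneficial range
    is the longest contiguous grid interval where the model beats both
    comparators; a run reaching the last grid point is reported up to 1.00.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if not 0 < grid_step < 1:
        raise ValueError("grid_step must be in (0,1)")
    grid = np.arange(grid_step, 1.0 - grid_step / 2, grid_step)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    n = len(y)
    pi = y.mean()
    odds = grid / (1.0 - grid)
    nb_model = np.empty_like(grid)
    for k, pt in enumerate(grid):
        pred = p >= pt
        tp = float((pred & (y == 1)).sum())
        fp = float((pred & (y == 0)).sum())
        nb_model[k] = tp / n - (fp / n) * odds[k]
    nb_all = pi - (1.0 - pi) * odds
    nb_none = np.zeros_like(grid)

    better = nb_model > np.maximum(nb_all, 0.0)
    rng = _longest_run(better)
    if rng is None:
        beneficial = None
    else:
        lo, hi = rng
        hi_val = 1.0 if hi == len(grid) - 1 else float(grid[hi])
        beneficial = (round(float(grid[lo]), 2), round(hi_val, 2))
    return DCAResult(grid, nb_model, nb_all, nb_none, beneficial)


def _longest_run(mask: np.ndarray):
    best, cur_start, best_len = None, None, 0
    for k, v in enumerate(np.append(mask, False)):
        if v and cur_start is None:
            cur_start = k
        elif not v and cur_start is not None:
            if k - cur_start > best_len:
                best_len = k - cur_start
                best = (cur_start, k - 1)
            cur_start = None
    return best


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    values: pd.Series
    mode: str
    degenerate: list[str] = field(default_factory=list)

    @property
    def minimum(self) -> float:
        return float(self.values.min())

    @property
    def maximum(self) -> float:
        return float(self.values.max())


def icc_single(ratings: np.ndarray, mode: str = "inter") -> tuple[float, bool]:
    """Single-measure ICC from a subjects x raters matrix.

    mode="inter" gives ICC(2,1), two-way random absolute agreement;
    mode="intra" gives ICC(3,1), two-way mixed consistency. Returns
    (value clamped to [-1, 1], degenerate flag for zero between-subject
    variance).
    """
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0:
        return 0.0, True
    if mode == "inter":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif mode == "intra":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC mode {mode!r}")
    if denom <= 0:
        return 0.0, True
    return float(np.clip((msr - mse) / denom, -1.0, 1.0)), False


def icc(ratings_by_feature: dict[str, np.ndarray], mode: str = "inter") -> ICCResult:
    """Per-feature ICCs plus min/max summary."""
    values, degenerate = {}, []
    for name, mat in ratings_by_feature.items():
        v, flag = icc_single(np.asarray(mat), mode)
        values[name] = v
        if flag:
            degenerate.append(name)
    return ICCResult(pd.Series(values), mode, degenerate)


# ---------------------------------------------------------------------------
# Spearman correlation screen
# ---------------------------------------------------------------------------


def spearman_feature_clinical(
    features: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Mid-rank Spearman rho with t-approximation p per (feature, covariate).

    Constant columns yield rho = NaN (flagged by the NaN itself).
    """
    rows = []
    for f in features.columns:
        for c in covariates.columns:
            x = features[f].to_numpy(dtype=float)
            z = covariates[c].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(z) == 0:
                rows.append((f, c, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(x, z)
            rows.append((f, c, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["feature", "covariate", "rho", "p"])
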