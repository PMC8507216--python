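"""Feature-selection cascade.

Four stages on the development cohort:

1. standardization to zero mean / unit (population) SD, with the fitted
   parameters frozen and re-applied unchanged to validation data,
2. univariate filtering: per feature, Shapiro-Wilk normality in each class
   routes to an equal-variance two-sample t-test (both classes normal) or a
   Mann-Whitney U test; keep p < alpha,
3. redundancy elimination: greedy by ascending univariate p, a feature is
   accepted iff |Spearman rho| < rho_max against every already-accepted one,
4. L1-penalized (LASSO) logistic regression with the penalty chosen as the
   minimizer of mean 10-fold cross-validated binomial deviance.

The survivor set of each stage is a subset of the previous stage's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._utils import DEFAULT_SEED

logger = logging.getLogger(__name__)


@dataclass
class StandardizationParams:
    """Development-cohort means/SDs; applied unchanged to any later table."""

    means: pd.Series
    sds: pd.Series
    excluded: list[str] = field(default_factory=list)  # zero-variance / non-finite

    @property
    def feature_names(self) -> list[str]:
        return list(self.means.index)


def standardize(dev_table: pd.DataFrame) -> tuple[StandardizationParams, pd.DataFrame]:
    """Fit standardization on the development table and transform it.

    Zero-variance and non-finite features are excluded (logged), never
    silently carried with SD 0.
    """
    if dev_table.empty:
        raise ValueError("development table is empty")
    finite = dev_table.columns[np.isfinite(dev_table).all(axis=0)]
    dropped = [c for c in dev_table.columns if c not in set(finite)]
    sub = dev_table[finite]
    sds = sub.std(ddof=0)
    zero_var = list(sds.index[sds == 0.0])
    dropped += zero_var
    keep = [c for c in finite if c not in set(zero_var)]
    if dropped:
        logger.warning("standardize: excluding %d degenerate features: %s",
                       len(dropped), dropped[:10])
    params = StandardizationParams(
        means=sub[keep].mean(), sds=sds[keep], excluded=dropped
    )
    return params, apply_standardization(params, dev_table)


def apply_standardization(params: StandardizationParams, table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in params.feature_names if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks standardized features: {missing[:5]}")
    return (table[params.feature_names] - params.means) / params.sds


def _route_test(x0: np.ndarray, x1: np.ndarray, normality_alpha: float = 0.05):
    """Shapiro-Wilk in each class decides t (both normal) vs Mann-Whitney."""
    normal = True
    for x in (x0, x1):
        if np.ptp(x) == 0:  # Shapiro undefined for constant data
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(x).pvalue < normality_alpha:
                normal = False
                break
    if normal:
        p = stats.ttest_ind(x0, x1, equal_var=True).pvalue
        return "t", float(p)
    if np.ptp(np.concatenate([x0, x1])) == 0:
        return "mannwhitney", 1.0
    p = stats.mannwhitneyu(x0, x1, alternative="two-sided", method="auto").pvalue
    return "mannwhitney", float(p)


def univariate_filter(
    table: pd.DataFrame, labels, alpha: float = 0.05, force_test: str | None = None
) -> pd.DataFrame:
    """Per-feature two-class test report: columns test, p, passed."""
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("univariate_filter needs exactly two classes")
    if min((y == c).sum() for c in classes) < 3:
        raise ValueError("each class needs at least 3 subjects")
    rows = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        x0, x1 = x[y == classes[0]], x[y == classes[1]]
        if force_test == "mannwhitney":
            test, p = "mannwhitney", float(
                stats.mannwhitneyu(x0, x1, alternative="two-sided", method="auto").pvalue
            )
        elif force_test == "t":
            test, p = "t", float(stats.ttest_ind(x0, x1, equal_var=True).pvalue)
        else:
            test, p = _route_test(x0, x1)
        if not np.isfinite(p):  # identical samples make the statistic undefined
            p = 1.0
        rows.append((name, test, p, p < alpha))
    return pd.DataFrame(rows, columns=["feature", "test", "p", "passed"]).set_index("feature")


def redundancy_filter(
    table: pd.DataFrame, report: pd.DataFrame, rho_max: float = 0.9
) -> list[str]:
    """Greedy Spearman de-duplication among univariate survivors.

    Candidates are visited in ascending univariate p (ties broken
    lexicographically by name) and accepted iff |rho| < rho_max against every
    already-accepted feature.
    """
    passed = report[report["passed"]]
    if passed.empty:
        return []
    order = passed.assign(_name=passed.index).sort_values(["p", "_name"], kind="mergesort")
    ranked = table[order.index].rank(method="average")
    accepted: list[str] = []
    for name in order.index:
        ok = True
        for prev in accepted:
            rho = ranked[name].corr(ranked[prev])  # Pearson of mid-ranks = Spearman
            if np.isfinite(rho) and abs(rho) >= rho_max:
                ok = False
                break
        if ok:
            accepted.append(name)
    return accepted


@dataclass
class LassoResult:
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    chosen_lambda: float
    intercept: float
    coefficients: dict[str, float]  # nonzero only
    fold_seed: int
    feature_names: list[str]

    @property
    def selected(self) -> list[str]:
        return list(self.coefficients)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_logistic_exact(X: np.ndarray, y: np.ndarray, lam: float):
    """L1 logistic with an unpenalized intercept via statsmodels.

    Objective: mean negative log-likelihood + lam * ||slopes||_1, so lam -> inf
    gives all-zero slopes and intercept = logit(prevalence); lam -> 0 gives
    the maximum-likelihood fit.
    """
    import statsmodels.api as sm

    n = len(y)
    # any penalty above the data's lambda_max already zeroes every slope, so
    # clamp to keep the optimizer well-conditioned without changing the fit
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / n if X.size else 1.0
    lam = min(lam, 10.0 * max(lam_max, 1e-12))
    Xc = sm.add_constant(X, has_constant="add")
    alpha = np.full(Xc.shape[1], lam * n)
    alpha[0] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit_regularized(
            method="l1", alpha=alpha, disp=False, trim_mode="auto",
            acc=1e-10, maxiter=2000,
        )
    params = np.asarray(res.params, dtype=float)
    return float(params[0]), params[1:]


def lasso_select(
    table: pd.DataFrame,
    labels,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
    lambda_override: float | None = None,
) -> LassoResult:
    """LASSO logistic selection at the CV-deviance-minimizing penalty.

    The cross-validated deviance path is computed with scikit-learn's
    liblinear solver; the final coefficients at the chosen penalty are refit
    with an exact unpenalized-intercept L1 optimizer. ``lambda_override``
    skips the CV search (used for limit checks).
    """
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain two classes")
    X = table.to_numpy(dtype=float)
    n = len(y)
    names = list(table.columns)

    if lambda_override is not None:
        lambdas = np.array([lambda_override])
        cv_dev = np.array([np.nan])
        chosen = float(lambda_override)
    else:
        ybar = y.mean()
        lam_max = np.abs(X.T @ (y - ybar)).max() / n
        lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - lambda_decades, n_lambdas)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
        folds = list(skf.split(X, y))
        # one warm-started solver per fold walks the descending lambda path;
        # held-out deviance is insensitive to tight solver tolerances and the
        # final coefficients are refit exactly below
        solvers = [
            LogisticRegression(
                penalty="elasticnet", l1_ratio=1.0, C=1.0, solver="saga",
                tol=1e-3, max_iter=200, warm_start=True, random_state=0,
            )
            for _ in folds
        ]
        cv_dev = np.full(n_lambdas, np.nan)
        best_j = 0
        for j, lam in enumerate(lambdas):
            fold_dev = []
            for clf, (tr, te) in zip(solvers, folds):
                clf.C = 1.0 / (len(tr) * lam)
                with warnings.catch_warnings():
                    # loose tol on the path is intentional; see refit below
                    warnings.simplefilter("ignore")
                    clf.fit(X[tr], y[tr])
                fold_dev.append(_binomial_deviance(y[te], clf.predict_proba(X[te])[:, 1]))
            cv_dev[j] = float(np.mean(fold_dev))
            if cv_dev[j] < cv_dev[best_j]:
                best_j = j
            # the deviance path is U-shaped: once it has clearly passed its
            # minimum, smaller penalties only overfit further
            if j - best_j > 10 and cv_dev[j] > cv_dev[best_j] * 1.05 + 0.02:
                break
        chosen = float(lambdas[best_j])

    intercept, coefs = _l1_logistic_exact(X, y, chosen)
    nz = {names[k]: float(coefs[k]) for k in range(len(names)) if coefs[k] != 0.0}
    return LassoResult(
        lambdas=lambdas,
        cv_deviance=cv_dev,
        chosen_lambda=chosen,
        intercept=intercept,
        coefficients=nz,
        fold_seed=seed,
        feature_names=names,
    )


def run_cascade(
    dev_table: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    rho_max: float = 0.9,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
    n_lambdas: int = 100,
    lambda_decades: float = 4.0,
):
    """Standardize -> univariate -> redundancy -> LASSO; returns all stages."""
    params, z = standardize(dev_table)
    report = univariate_filter(z, labels, alpha=alpha)
    survivors = redundancy_filter(z, report, rho_max=rho_max)
    if not survivors:
        raise ValueError("no features survived univariate + redundancy filtering")
    lasso = lasso_select(
        z[survivors], labels, n_folds=n_folds, seed=seed,
        n_lambdas=n_lambdas, lambda_decades=lambda_decades,
    )
    return params, report, survivors, lasso
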