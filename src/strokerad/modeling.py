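"""Rad-score, clinical-variable screening, and the combined logistic model.

The rad-score is the linear predictor of the selected standardized features
(intercept + sum of coefficient * standardized value). By default the LASSO
coefficients are used directly; a refit mode re-estimates unpenalized
logistic coefficients on the selected features. Validation subjects are
always scored with development-derived standardization and coefficients.

The positive class throughout is the early stratum (onset <= 4.5 h).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selection import LassoResult, StandardizationParams, apply_standardization

logger = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = ("age", "nihss", "aspects")
ORDINAL_COVARIATES = ("collateral_grade",)
CATEGORICAL_COVARIATES = (
    "sex",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "atrial_fibrillation",
    "smoking",
    "alcohol",
    "hvs",
    "ica_occlusion",
    "side",
)


@dataclass
class RadScoreModel:
    intercept: float
    coefficients: dict[str, float]
    standardization: StandardizationParams
    source: str = "lasso"  # {lasso, refit}

    @classmethod
    def from_lasso(
        cls,
        lasso: LassoResult,
        params: StandardizationParams,
        refit: bool = False,
        dev_table: pd.DataFrame | None = None,
        labels=None,
    ) -> "RadScoreModel":
        if not refit:
            return cls(lasso.intercept, dict(lasso.coefficients), params, "lasso")
        if dev_table is None or labels is None:
            raise ValueError("refit mode needs the development table and labels")
        import statsmodels.api as sm

        z = apply_standardization(params, dev_table)[list(lasso.coefficients)]
        X = sm.add_constant(z.to_numpy(dtype=float), has_constant="add")
        res = sm.Logit(np.asarray(labels).astype(int), X).fit(disp=False)
        coefs = dict(zip(lasso.coefficients, map(float, res.params[1:])))
        return cls(float(res.params[0]), coefs, params, "refit")


def compute_radscore(model: RadScoreModel, features) -> float | pd.Series:
    """Linear predictor on standardized features.

    Accepts a single mapping (returns float) or a DataFrame (returns Series).
    """
    names = list(model.coefficients)
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise KeyError(f"feature vector lacks {missing}")
        z = apply_standardization(model.standardization, features)
        score = model.intercept + z[names].to_numpy(dtype=float) @ np.array(
            [model.coefficients[n] for n in names]
        )
        return pd.Series(score, index=features.index, name="radscore")
    missing = [n for n in names if n not in features]
    if missing:
        raise KeyError(f"feature vector lacks {missing}")
    total = model.intercept
    for n in names:
        mu = model.standardization.means[n]
        sd = model.standardization.sds[n]
        total += model.coefficients[n] * (float(features[n]) - mu) / sd
    return float(total)


def _chi2_or_fisher(x: np.ndarray, y: np.ndarray) -> tuple[str, float]:
    """Pearson chi-square (no continuity correction); Fisher if expected < 5."""
    tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return "chi2", 1.0  # constant covariate
    expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    if tab.shape == (2, 2) and expected.min() < 5:
        return "fisher", float(stats.fisher_exact(tab).pvalue)
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return "chi2", float(p)


def _continuous_test(x0: np.ndarray, x1: np.ndarray) -> tuple[str, float]:
    from .selection import _route_test

    return _route_test(x0, x1)


def screen_clinical(
    covariates: pd.DataFrame, labels, alpha: float = 0.05
) -> pd.DataFrame:
    """Univariate screen of clinicoradiological variables against the label.

    Continuous variables route by per-class Shapiro-Wilk normality to the
    equal-variance t-test or Mann-Whitney; ordinal variables use
    Mann-Whitney; categorical variables use the Pearson chi-square (Fisher
    exact when any expected cell < 5). Returns a report with ``selected``
    = (p < alpha); constant covariates get p = 1.
    """
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("two classes required")
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        if name in CATEGORICAL_COVARIATES or col.dtype == bool or col.dtype == object:
            test, p = _chi2_or_fisher(col.to_numpy(), y)
        else:
            x = col.to_numpy(dtype=float)
            x0, x1 = x[y == 0], x[y == 1]
            if np.ptp(x) == 0:
                test, p = "constant", 1.0
            elif name in ORDINAL_COVARIATES:
                test = "mannwhitney"
                p = float(stats.mannwhitneyu(x0, x1, alternative="two-sided", method="auto").pvalue)
            else:
                test, p = _continuous_test(x0, x1)
        if not np.isfinite(p):
            p = 1.0
        rows.append((name, test, p, p < alpha))
    return pd.DataFrame(rows, columns=["variable", "test", "p", "selected"]).set_index("variable")


@dataclass
class CombinedModel:
    """Logistic model over the rad-score and screened clinical variables."""

    intercept: float
    coefficients: dict[str, float]
    separation_fallback: bool = False
    covariate_names: list[str] = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        names = list(self.coefficients)
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing model inputs: {missing}")
        beta = np.array([self.coefficients[n] for n in names])
        return self.intercept + X[names].to_numpy(dtype=float) @ beta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(X)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_combined(
    radscores: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
    labels,
    ridge_fallback: float = 1e-6,
) -> CombinedModel:
    """Maximum-likelihood logistic fit of label ~ radscore + covariates.

    Perfect separation (or otherwise unbounded coefficients) triggers a
    documented ridge fallback with penalty ``ridge_fallback`` and sets the
    ``separation_fallback`` flag.
    """
    import statsmodels.api as sm

    y = np.asarray(labels).astype(int)
    X = pd.DataFrame({"radscore": np.asarray(radscores, dtype=float)})
    if covariates is not None and len(covariates.columns):
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy(dtype=float)
    if X.isna().any().any():
        raise ValueError("missing values in model inputs")
    names = list(X.columns)
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            raise np.linalg.LinAlgError("unbounded coefficients")
    except Exception:
        fallback = True
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(
            C=1.0 / (len(y) * ridge_fallback), solver="lbfgs", max_iter=5000
        )
        clf.fit(X.to_numpy(dtype=float), y)
        params = np.concatenate([[clf.intercept_[0]], clf.coef_[0]])
        logger.warning("fit_combined: perfect separation, ridge fallback %.0e applied",
                       ridge_fallback)
    return CombinedModel(
        intercept=float(params[0]),
        coefficients=dict(zip(names, map(float, params[1:]))),
        separation_fallback=fallback,
        covariate_names=names[1:],
    )


@dataclass
class CalibrationResult:
    statistic: float
    groups: int
    df: int
    p: float


def hosmer_lemeshow(probs, labels, g: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow grouped calibration test.

    Subjects are split into ``g`` equal-frequency groups of predicted risk
    (ties grouped); the statistic sums (O - E)^2 / (E (1 - E / n_g)) over
    groups and is referred to chi-square with g - 2 degrees of freedom.
    Probabilities are clipped to [1e-6, 1 - 1e-6] so that a group of
    (near-)certain but wrong predictions registers as gross miscalibration
    (p ~ 0) instead of a division by zero.
    """
    p = np.clip(np.asarray(probs, dtype=float), 1e-6, 1.0 - 1e-6)
    y = np.asarray(labels).astype(int)
    if len(p) < 2 * g:
        raise ValueError(f"need at least {2 * g} subjects for g={g}")
    bins = pd.qcut(p, g, duplicates="drop")
    groups = pd.DataFrame({"p": p, "y": y, "bin": bins}).groupby("bin", observed=True)
    stat = 0.0
    n_groups = 0
    for _, grp in groups:
        n_g = len(grp)
        if n_g == 0:
            continue
        O = grp["y"].sum()
        E = grp["p"].sum()
        denom = E * (1.0 - E / n_g)
        if denom <= 1e-12:
            # a group of (near-)certain predictions has zero expected
            # variance; it contributes nothing when observed matches expected
            if abs(O - E) > 1e-6:
                raise ValueError("group with zero expected count but nonzero residual")
            n_groups += 1
            continue
        stat += (O - E) ** 2 / denom
        n_groups += 1
    df = n_groups - 2
    pval = float(stats.chi2.sf(stat, df))
    return CalibrationResult(float(stat), n_groups, df, pval)
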