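"""Correlation screen, regression battery and variance decomposition.

The prediction analysis proceeds in three steps:

1. a univariate Pearson screen of every candidate covariate (age, sex,
   lesion location, CST injury, lesion volume, initial FMA) against the
   follow-up FMA score;
2. simple and multiple linear regression with *standardized* coefficients
   (for a single predictor the standardized slope equals Pearson's r, so
   R^2 = beta^2), adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1), and for
   each predictor the partial and semipartial (part) correlation obtained
   by residualizing on the remaining predictors.  The squared part
   correlation is the predictor's *unique contribution* to R^2;
3. a multicollinearity check: the partial correlation between two
   predictors controlling for the screened-out covariates; collinearity is
   called absent when that partial correlation is not significant at
   alpha = 0.05.

Two-sided p-values throughout; no multiple-testing correction is applied
(deliberately, to keep the battery a faithful reproduction of the screening
procedure it models).  OLS fits go through statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationScreen",
    "RegressionReport",
    "CollinearityCheck",
    "adjusted_r2",
    "pearson_screen",
    "simple_regression",
    "multiple_regression",
    "collinearity_check",
    "partial_correlation",
    "limb_battery",
    "SCREEN_COVARIATES",
    "LIMB_COLUMNS",
]

ALPHA = 0.05

#: default covariate battery for the screen (binary covariates are coded
#: 0/1; the coding is configurable and only affects signs)
SCREEN_COVARIATES = ("age", "sex", "lesion_location", "cst_injury", "lesion_volume", "initial_fma")
BINARY_CODING = {"sex": {"M": 0, "F": 1}, "lesion_location": {"cortical": 0, "subcortical": 1}}


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class CorrelationScreen:
    """Univariate Pearson r of each covariate with the outcome."""

    table: pd.DataFrame  # columns: covariate, r, p, significant
    alpha: float = ALPHA

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "covariate"])


@dataclass(frozen=True)
class RegressionReport:
    """Standardized regression output with variance decomposition.

    ``beta`` are standardized coefficients; ``partial``/``part`` are the
    partial and semipartial correlations of each predictor with the
    outcome; ``unique_contribution = part**2`` is the share of outcome
    variance explained by that predictor alone.
    """

    predictors: tuple[str, ...]
    beta: dict[str, float]
    p_values: dict[str, float]
    partial: dict[str, float]
    part: dict[str, float]
    r2: float
    adj_r2: float
    n: int

    @property
    def unique_contribution(self) -> dict[str, float]:
        return {k: v**2 for k, v in self.part.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.predictors),
                "beta": [self.beta[k] for k in self.predictors],
                "p": [self.p_values[k] for k in self.predictors],
                "partial": [self.partial[k] for k in self.predictors],
                "part": [self.part[k] for k in self.predictors],
                "unique_contribution": [self.unique_contribution[k] for k in self.predictors],
            }
        )


@dataclass(frozen=True)
class CollinearityCheck:
    r: float
    p: float
    n: int
    n_controls: int
    alpha: float = ALPHA

    @property
    def verdict(self) -> str:
        """'absent' iff the partial correlation is not significant."""
        return "absent" if self.p >= self.alpha else "present"


def _code_binary(values: pd.Series, name: str) -> np.ndarray:
    if values.dtype.kind in "ifub":
        return values.to_numpy(dtype=float)
    coding = BINARY_CODING.get(name)
    if coding is None:
        raise ValueError(f"no coding known for non-numeric covariate {name!r}")
    return values.map(coding).to_numpy(dtype=float)


def pearson_screen(
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    alpha: float = ALPHA,
) -> CorrelationScreen:
    """Univariate Pearson correlation of each covariate with the outcome.

    Zero-variance covariates yield an undefined r; they are reported as
    NaN / not significant with a warning rather than failing the screen.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) < 3:
        raise ValueError("need n >= 3 for a correlation screen")
    rows = []
    for name in covariates.columns:
        x = _code_binary(covariates[name], name)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name!r} has zero variance; r undefined")
            rows.append({"covariate": name, "r": np.nan, "p": np.nan, "significant": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"covariate": name, "r": r, "p": p, "significant": bool(p < alpha)})
    return CorrelationScreen(table=pd.DataFrame(rows), alpha=alpha)


def simple_regression(x: np.ndarray, y: np.ndarray) -> RegressionReport:
    """Single-predictor regression with standardized slope (= Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    r, p = stats.pearsonr(x, y)
    r2 = r**2
    name = "x"
    return RegressionReport(
        predictors=(name,),
        beta={name: r},
        p_values={name: p},
        partial={name: r},
        part={name: r},
        r2=r2,
        adj_r2=adjusted_r2(r2, n, 1),
        n=n,
    )


def _residualize(target: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """OLS residuals of target on controls (with intercept)."""
    X = np.column_stack([np.ones(len(target)), controls]) if controls.size else np.ones((len(target), 1))
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    return target - X @ coef


def multiple_regression(y: np.ndarray | pd.Series, predictors: pd.DataFrame) -> RegressionReport:
    """Multiple OLS with standardized coefficients and partial/part correlations.

    The partial correlation of predictor j is the correlation between the
    outcome and predictor after residualizing *both* on the remaining
    predictors; the part (semipartial) correlation residualizes only the
    predictor.  ``unique_contribution`` (part^2) is the drop in R^2 when
    predictor j is removed from the model.
    """
    y = np.asarray(y, dtype=float)
    names = tuple(predictors.columns)
    X = np.column_stack([_code_binary(predictors[c], c) for c in names])
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear predictors: {pairs or names}")

    zx = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(zy, sm.add_constant(zx)).fit()
    beta = dict(zip(names, model.params[1:]))
    pvals = dict(zip(names, model.pvalues[1:]))
    r2 = float(model.rsquared)

    partial, part = {}, {}
    y_sd = np.std(y, ddof=1)
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        xr = _residualize(X[:, j].astype(float), others)
        yr = _residualize(y, others)
        partial[name] = float(np.corrcoef(xr, yr)[0, 1])
        part[name] = float(np.corrcoef(xr, y)[0, 1]) if y_sd > 0 else np.nan
    return RegressionReport(
        predictors=names,
        beta={k: float(v) for k, v in beta.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        partial=partial,
        part=part,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p),
        n=n,
    )


def partial_correlation(
    x1: np.ndarray, x2: np.ndarray, controls: np.ndarray | pd.DataFrame | None
) -> tuple[float, float, int]:
    """Partial correlation of x1 and x2 given controls, with two-sided p.

    Computed by residualizing both variables on the controls; the p-value
    uses the t distribution with n - k - 2 degrees of freedom, k the
    number of controls.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if controls is None:
        C = np.empty((len(x1), 0))
    elif isinstance(controls, pd.DataFrame):
        C = np.column_stack([_code_binary(controls[c], c) for c in controls.columns])
    else:
        C = np.asarray(controls, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    n, k = len(x1), C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    r1 = _residualize(x1, C)
    r2_ = _residualize(x2, C)
    r = float(np.corrcoef(r1, r2_)[0, 1])
    df = n - k - 2
    r_clipped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clipped * np.sqrt(df / (1 - r_clipped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p, n


LIMB_COLUMNS = {
    "UE": ("initial_fma_ue", "followup_fma_ue"),
    "LE": ("initial_fma_le", "followup_fma_le"),
}


def limb_battery(cohort: pd.DataFrame, limb: str, alpha: float = ALPHA) -> dict:
    """The full screen-then-regress battery for one limb on one cohort.

    Runs the univariate Pearson screen of the standard covariate set
    against the follow-up score, the simple regression of follow-up on CST
    injury, a multiple regression on the screen-significant covariates, and
    (when at least two covariates enter) the partial-correlation
    multicollinearity check of the first two included predictors
    controlling for the screened-out ones.
    """
    init_col, follow_col = LIMB_COLUMNS[limb]
    y = cohort[follow_col].to_numpy(dtype=float)
    covs = pd.DataFrame(
        {
            "age": cohort["age"],
            "sex": cohort["sex"],
            "lesion_location": cohort["lesion_location"],
            "cst_injury": cohort["cst_injury"],
            "lesion_volume": cohort["lesion_volume_mm3"],
            "initial_fma": cohort[init_col],
        }
    )
    screen = pearson_screen(y, covs, alpha=alpha)
    simple = simple_regression(cohort["cst_injury"].to_numpy(dtype=float), y)
    included = screen.significant
    multiple = None
    collinearity = None
    if included:
        multiple = multiple_regression(y, covs[included])
        if len(included) >= 2:
            excluded = [c for c in covs.columns if c not in included]
            collinearity = collinearity_check(
                _code_binary(covs[included[0]], included[0]),
                _code_binary(covs[included[1]], included[1]),
                covs[excluded] if excluded else None,
                alpha=alpha,
            )
    return {
        "limb": limb,
        "n": len(cohort),
        "screen": screen,
        "simple_injury": simple,
        "multiple": multiple,
        "collinearity": collinearity,
    }


def collinearity_check(
    x1: np.ndarray,
    x2: np.ndarray,
    controls: pd.DataFrame | np.ndarray | None,
    alpha: float = ALPHA,
) -> CollinearityCheck:
    """Partial-correlation multicollinearity check between two predictors."""
    r, p, n = partial_correlation(x1, x2, controls)
    if controls is None:
        k = 0
    elif isinstance(controls, pd.DataFrame):
        k = len(controls.columns)
    else:
        arr = np.asarray(controls)
        k = 1 if arr.ndim == 1 else arr.shape[1]
    return CollinearityCheck(r=r, p=p, n=n, n_controls=k, alpha=alpha)
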