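"""Driver attribution of greenspace exposure inequality across cities.

Given a table of cities with an exposure Gini response and 16 candidate
covariates (geography, topography, climate, socioeconomics, greenspace
landscape), this module:

1. min-max rescales covariates to [0, 1] (the response stays raw);
2. screens covariates by Pearson correlation with the response, its
   two-sided p-value, and the partial correlation controlling for all
   other covariates (|r| > 0.1, p < 0.001, |partial r| > 0.1);
3. fits nested OLS models — geography alone, climate alone, landscape
   alone, and all together — reporting raw-scale and standardized
   coefficients, p-values, and adjusted R^2;
4. checks multicollinearity by variance inflation factors; and
5. partitions the explained variance of the Gini into the unique effect of
   greenspace provision (coverage rate), the unique effect of configuration
   (edge density), their joint effect, and the unexplained residual,
   following the commonality-analysis convention of R's vegan::varpart
   (adjusted R^2 by default; joint fractions can legitimately be negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

from .synthetic import COVARIATE_NAMES

__all__ = [
    "DEFAULT_MODEL_SPECS",
    "VariancePartition",
    "rescale_01",
    "screen_variables",
    "ols_nested",
    "vif",
    "variance_partition",
]

#: The four nested regression models: geography, climate, landscape, full.
DEFAULT_MODEL_SPECS = {
    "model_1": ["lat"],
    "model_2": ["prcp", "vpd"],
    "model_3": ["gcr", "ed"],
    "model_4": ["lat", "prcp", "vpd", "gcr", "ed"],
}

RESPONSE = "gini"


@dataclass
class VariancePartition:
    unique_provision: float
    unique_configuration: float
    joint: float
    residual: float

    def as_dict(self) -> dict[str, float]:
        return {
            "unique_provision": self.unique_provision,
            "unique_configuration": self.unique_configuration,
            "joint": self.joint,
            "residual": self.residual,
        }


def _covariates_of(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != RESPONSE]


def rescale_01(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Min-max rescale every covariate to [0, 1]; response left raw.

    Returns the rescaled table and the list of constant (max == min)
    covariates, which are mapped to 0 and must be excluded from screening.
    """
    out = table.copy()
    flagged: list[str] = []
    for col in _covariates_of(table):
        lo, hi = table[col].min(), table[col].max()
        if hi > lo:
            out[col] = (table[col] - lo) / (hi - lo)
        else:
            out[col] = 0.0
            flagged.append(col)
    return out, flagged


def partial_correlation(
    table: pd.DataFrame, x: str, y: str, controls: list[str]
) -> tuple[float, float]:
    """Partial correlation of x and y given controls, with two-sided p.

    With an empty control set this is the plain Pearson correlation.
    """
    if not controls:
        r, p = stats.pearsonr(table[x], table[y])
        return float(r), float(p)
    res = pg.partial_corr(data=table, x=x, y=y, covar=list(controls))
    pcol = "p_val" if "p_val" in res.columns else "p-val"
    return float(res["r"].iloc[0]), float(res[pcol].iloc[0])


def screen_variables(
    table: pd.DataFrame,
    p_threshold: float = 0.001,
    r_threshold: float = 0.1,
    partial_threshold: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Correlation screening of candidate drivers.

    For each covariate: Pearson r against the response with two-sided p,
    and the partial correlation controlling for all other covariates. A
    covariate is selected when p < ``p_threshold``, |r| > ``r_threshold``
    and |partial r| > ``partial_threshold``. Returns the selected names
    (in table column order) and the full report.
    """
    if len(table) < 20:
        raise ValueError("screening needs at least 20 rows to be stable")
    scaled, flagged = rescale_01(table)
    covs = [c for c in _covariates_of(scaled) if c not in flagged]
    rows = []
    for cov in covs:
        r, p = stats.pearsonr(scaled[cov], scaled[RESPONSE])
        controls = [c for c in covs if c != cov]
        try:
            pr, _ = partial_correlation(scaled, cov, RESPONSE, controls)
            excluded = False
        except np.linalg.LinAlgError:
            pr, excluded = np.nan, True
        selected = (
            not excluded
            and p < p_threshold
            and abs(r) > r_threshold
            and abs(pr) > partial_threshold
        )
        rows.append({"covariate": cov, "pearson_r": r, "p_value": p,
                     "partial_r": pr, "selected": selected,
                     "excluded": excluded})
    report = pd.DataFrame(rows)
    selected = report.loc[report["selected"], "covariate"].tolist()
    return selected, report


def _fit_ols(table: pd.DataFrame, covariates: list[str]):
    y = table[RESPONSE].to_numpy(dtype=float)
    X = sm.add_constant(table[list(covariates)].to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: collinear covariate set {covariates}"
        )
    return sm.OLS(y, X).fit()


def ols_nested(
    table: pd.DataFrame,
    model_specs: dict[str, list[str]] | None = None,
) -> dict[str, dict]:
    """Fit the nested OLS models on rescaled covariates, raw response.

    Per model: intercept and per-covariate raw-scale coefficients (on the
    [0, 1] covariate scale), standard errors, two-sided p-values,
    standardized (z-score) coefficients, and raw/adjusted R^2.
    """
    model_specs = model_specs or DEFAULT_MODEL_SPECS
    scaled, _ = rescale_01(table)
    missing = {c for covs in model_specs.values() for c in covs} - set(
        scaled.columns
    )
    if missing:
        raise ValueError(f"model specs reference unknown covariates: "
                         f"{sorted(missing)}")
    results: dict[str, dict] = {}
    y_sd = scaled[RESPONSE].std(ddof=1)
    for name, covs in model_specs.items():
        if len(table) <= len(covs) + 1:
            raise ValueError(f"{name}: need n > p + 1")
        fit = _fit_ols(scaled, covs)
        coefs = dict(zip(["intercept"] + list(covs), fit.params))
        std_coefs = {
            c: fit.params[i + 1] * scaled[c].std(ddof=1) / y_sd
            for i, c in enumerate(covs)
        }
        results[name] = {
            "covariates": list(covs),
            "coefficients": coefs,
            "std_errors": dict(zip(["intercept"] + list(covs), fit.bse)),
            "standardized_coefficients": std_coefs,
            "p_values": dict(zip(["intercept"] + list(covs), fit.pvalues)),
            "r_squared": float(fit.rsquared),
            "adjusted_r_squared": float(fit.rsquared_adj),
            "n": int(fit.nobs),
        }
    return results


def vif(table: pd.DataFrame, covariates: list[str]) -> dict[str, float]:
    """Variance inflation factor per covariate: 1 / (1 - R^2_j).

    R^2_j comes from regressing covariate j on the remaining covariates.
    Perfectly collinear covariates get ``inf``.
    """
    if len(covariates) < 2:
        raise ValueError("vif needs at least 2 covariates")
    if len(table) <= len(covariates) + 1:
        raise ValueError("vif needs n > p + 1")
    out: dict[str, float] = {}
    X = table[list(covariates)].to_numpy(dtype=float)
    for j, cov in enumerate(covariates):
        others = np.delete(X, j, axis=1)
        fit = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(float(fit.rsquared), 1.0)
        out[cov] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out


def variance_partition(
    table: pd.DataFrame,
    set_a: list[str] = ("gcr",),
    set_b: list[str] = ("ed",),
    adjusted: bool = True,
) -> VariancePartition:
    """Two-set commonality analysis of the Gini response.

    With R2_a, R2_b, R2_ab the (adjusted) R^2 of fits on A, B and A∪B:

        unique_a = R2_ab − R2_b,  unique_b = R2_ab − R2_a,
        joint    = R2_a + R2_b − R2_ab,  residual = 1 − R2_ab.

    The four fractions sum to 1 by construction. The joint fraction may be
    negative (suppression); it is reported as-is.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both covariate sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("covariate sets must be disjoint")
    scaled, _ = rescale_01(table)
    attr = "rsquared_adj" if adjusted else "rsquared"
    r2_a = float(getattr(_fit_ols(scaled, set_a), attr))
    r2_b = float(getattr(_fit_ols(scaled, set_b), attr))
    r2_ab = float(getattr(_fit_ols(scaled, set_a + set_b), attr))
    return VariancePartition(
        unique_provision=r2_ab - r2_b,
        unique_configuration=r2_ab - r2_a,
        joint=r2_a + r2_b - r2_ab,
        residual=1.0 - r2_ab,
    )
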