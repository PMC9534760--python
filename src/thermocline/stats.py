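"""The inferential battery used around the divergence and vulnerability
analyses: OLS linear/quadratic regressions, one-way ANCOVA with body mass
as covariate, two-way fixed-effects ANOVA of acclimation experiments,
paired t, and the two-sample Kolmogorov–Smirnov test.

Model fitting is delegated to statsmodels/scipy; this module fixes the
contracts (which F is reported, which sums of squares, which p-value
method) so results are comparable across analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ModelFit",
    "TestResult",
    "ols_fit",
    "paired_t",
    "ks_two_sample",
    "ancova_population_mass",
    "anova_two_way",
]


@dataclass(frozen=True)
class ModelFit:
    """A fitted regression with its overall (or partial) F-test."""

    coefficients: dict[str, float]
    r2: float
    f_stat: float
    df: tuple[float, float]
    p_value: float
    residuals: np.ndarray
    method: str = "ols"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    method: str


def ols_fit(y, x, degree: int = 1) -> ModelFit:
    """Least-squares polynomial regression of y on x with intercept.

    Reports named coefficients (intercept, x, x2, ...), R-squared and the
    overall F-test with df (degree, n - degree - 1).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = len(y)
    if n <= degree + 1:
        raise ValueError("need n > degree + 1 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: rank-deficient design")
    X = np.column_stack([x**d for d in range(1, degree + 1)])
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    names = ["intercept"] + ["x" if d == 1 else f"x{d}" for d in range(1, degree + 1)]
    return ModelFit(
        coefficients=dict(zip(names, fit.params)),
        r2=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        residuals=np.asarray(fit.resid),
    )


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test on x - y (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    if np.ptp(d) == 0 and d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic), df=float(len(x) - 1),
        p_value=float(res.pvalue), method="paired t",
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov with the asymptotic p-value.

    D is the supremum distance between the two empirical CDFs over the
    pooled support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(
        statistic=float(res.statistic), df=None,
        p_value=float(res.pvalue), method="two-sample KS (asymptotic)",
    )


def ancova_population_mass(
    traits: pd.DataFrame, trait: str | None = None, value_col: str = "value_c"
) -> dict[str, ModelFit]:
    """ANCOVA ``value ~ population + mass``: partial F-tests for both terms.

    Returns {"population": ..., "mass": ...}; the population fit carries
    the partial (Type II) F-test for the factor given mass, with the model
    R-squared and residuals.
    """
    df = traits
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    df = df.rename(columns={value_col: "value"})[["value", "population", "mass_mg"]].dropna()
    if df["population"].nunique() < 2:
        raise ValueError("need >= 2 populations")
    k = df["population"].nunique()
    n = len(df)
    if n - k - 1 <= 0:
        raise ValueError("no residual degrees of freedom")
    fit = smf.ols("value ~ C(population) + mass_mg", data=df).fit()
    table = anova_lm(fit, typ=2)
    out = {}
    for term, name in (("C(population)", "population"), ("mass_mg", "mass")):
        out[name] = ModelFit(
            coefficients=dict(fit.params),
            r2=float(fit.rsquared),
            f_stat=float(table.loc[term, "F"]),
            df=(float(table.loc[term, "df"]), float(table.loc["Residual", "df"])),
            p_value=float(table.loc[term, "PR(>F)"]),
            residuals=np.asarray(fit.resid),
            method="ancova (type II partial F)",
        )
    return out


def anova_two_way(
    table: pd.DataFrame, trait: str | None = None, value_col: str = "value_c"
) -> pd.DataFrame:
    """Sequential (Type I) two-way ANOVA: population, temperature, interaction.

    Rows in fitting order — population, acclimation temperature, their
    interaction, residual — each with df, sums of squares, mean squares
    and F against the residual mean square. Every factor cell must be
    non-empty.
    """
    df = table
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    df = df.rename(columns={value_col: "value"})[["value", "population", "acclimation_c"]]
    if df["population"].nunique() < 2 or df["acclimation_c"].nunique() < 2:
        raise ValueError("need >= 2 levels in each factor")
    cells = df.groupby(["population", "acclimation_c"]).size()
    full = pd.MultiIndex.from_product(
        [df["population"].unique(), df["acclimation_c"].unique()]
    )
    empty = full.difference(cells.index)
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty)[:5]}")
    fit = smf.ols("value ~ C(population) * C(acclimation_c)", data=df).fit()
    tab = anova_lm(fit, typ=1)
    tab = tab.rename(
        index={
            "C(population)": "population",
            "C(acclimation_c)": "temperature",
            "C(population):C(acclimation_c)": "interaction",
            "Residual": "residual",
        }
    )
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    return tab[["df", "sum_sq", "mean_sq", "F", "PR(>F)"]]
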