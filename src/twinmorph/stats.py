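"""Covariate-adjusted scalar statistics for trait and ROI analyses.

All group-level comparisons in this package reduce to ordinary least squares
with covariates: the adjusted two-sample t test is the t of a 0/1 group dummy,
the ANCOVA F comes from a nested-model comparison, and partial correlations
are recovered from the regression t as r = t / sqrt(t^2 + df).  Categorical
covariates (site, scanner, race) enter as one-hot dummies with the first
level as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class RegressionResult:
    """Slope of a predictor adjusted for covariates, with inference."""

    beta: float
    se: float
    t: float
    df: int
    p: float
    partial_r: float
    n: int
    covariates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "se": self.se, "t": self.t, "df": self.df,
            "p": self.p, "partial_r": self.partial_r, "n": self.n,
            "covariates": list(self.covariates),
        }


@dataclass
class SlopeTestResult:
    """Test of equality of two independently estimated slopes."""

    t: float
    df: int
    p: float
    slope1: float
    slope2: float
    se1: float
    se2: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "slope1": self.slope1, "slope2": self.slope2,
                "se1": self.se1, "se2": self.se2}


@dataclass
class EffectSize:
    """Cohen's d derived from a t statistic."""

    d: float
    method: str
    inputs: dict = field(default_factory=dict)


def build_covariate_matrix(
    table: pd.DataFrame,
    covariates: list[str] | None,
    categorical: tuple[str, ...] = ("site_id", "scanner_id", "race", "zygosity"),
) -> pd.DataFrame:
    """One-hot encode categorical covariates, keep numeric ones as-is.

    First level of each categorical is the reference (dropped).
    """
    if not covariates:
        return pd.DataFrame(index=table.index)
    cols = []
    for name in covariates:
        col = table[name]
        if name in categorical or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame(name))
    return pd.concat(cols, axis=1)


def _as_design(covariate_matrix) -> tuple[np.ndarray, list[str]]:
    if covariate_matrix is None:
        return np.empty((0, 0)), []
    if isinstance(covariate_matrix, pd.DataFrame):
        return covariate_matrix.to_numpy(dtype=float), list(covariate_matrix.columns)
    arr = np.asarray(covariate_matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    names = [f"cov{i}" for i in range(arr.shape[1])]
    return arr, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved: drop each and see whether rank recovers
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise CollinearityError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def adjusted_regression(outcome, predictor, covariate_matrix=None) -> RegressionResult:
    """OLS slope of ``predictor`` on ``outcome`` adjusted for covariates.

    The partial correlation between predictor and outcome given the
    covariates is recovered as t / sqrt(t^2 + df).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    Z, names = _as_design(covariate_matrix)
    n = y.size
    parts = [np.ones((n, 1)), x[:, None]]
    if Z.size:
        parts.append(Z)
    X = np.hstack(parts)
    if n <= X.shape[1]:
        raise ValueError(f"n={n} too small for {X.shape[1]} coefficients")
    _check_rank(X, ["const", "predictor"] + names)
    model = sm.OLS(y, X).fit()
    t = float(model.tvalues[1])
    df = int(model.df_resid)
    return RegressionResult(
        beta=float(model.params[1]),
        se=float(model.bse[1]),
        t=t,
        df=df,
        p=float(model.pvalues[1]),
        partial_r=t / np.sqrt(t * t + df),
        n=n,
        covariates=names,
    )


def adjusted_two_sample_t(outcome, groups, covariate_matrix=None) -> RegressionResult:
    """Two-sample t test with covariates, as the regression t of a group dummy.

    With no covariates this equals the classic pooled-variance t test.  The
    returned t is for the second group level (sorted order) coded 1.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    dummy = (groups == levels[1]).astype(float)
    return adjusted_regression(outcome, dummy, covariate_matrix)


def slope_test(res1: RegressionResult, res2: RegressionResult) -> SlopeTestResult:
    """Compare two independently estimated slopes.

    t = (b1 - b2) / sqrt(se1^2 + se2^2), df = n1 + n2 - 2(k+1) where k is the
    common number of non-intercept coefficients.
    """
    k1 = 1 + len(res1.covariates)
    k2 = 1 + len(res2.covariates)
    if k1 != k2:
        warnings.warn("slope_test: models have different coefficient counts")
    se = np.sqrt(res1.se**2 + res2.se**2)
    t = (res1.beta - res2.beta) / se if se > 0 else 0.0
    df = res1.n + res2.n - 2 * (k1 + 1)
    p = 2.0 * sps.t.sf(abs(t), df)
    return SlopeTestResult(t=float(t), df=int(df), p=float(p),
                           slope1=res1.beta, slope2=res2.beta,
                           se1=res1.se, se2=res2.se)


def cohen_d_from_t(t: float, df: float) -> EffectSize:
    """Cohen's d approximated from a t statistic: d = 2t / sqrt(df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return EffectSize(d=2.0 * t / np.sqrt(df), method="from_t",
                      inputs={"t": t, "df": df})


def cohen_d_two_sample(t: float, n1: int, n2: int) -> EffectSize:
    """Two-sample Cohen's d from t: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    return EffectSize(d=t * np.sqrt(1.0 / n1 + 1.0 / n2), method="two_sample",
                      inputs={"t": t, "n1": n1, "n2": n2})


def ancova(outcome, groups, covariate_matrix=None) -> tuple[float, float]:
    """F test for a group factor adjusting for covariates.

    Nested-model comparison: full model with group dummies + covariates
    against the reduced model with covariates only.  Returns (F, p).
    """
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("ancova requires at least 2 groups")
    G = np.column_stack([(groups == lv).astype(float) for lv in levels[1:]])
    Z, _ = _as_design(covariate_matrix)
    n = y.size
    base = [np.ones((n, 1))]
    if Z.size:
        base.append(Z)
    X0 = np.hstack(base)
    X1 = np.hstack(base + [G])
    rss0 = sm.OLS(y, X0).fit().ssr
    full = sm.OLS(y, X1).fit()
    rss1 = full.ssr
    q = levels.size - 1
    df_resid = full.df_resid
    F = ((rss0 - rss1) / q) / (rss1 / df_resid)
    p = float(sps.f.sf(F, q, df_resid))
    return float(F), p


def interaction_test(outcome, sex, predictor, family_ids, covariate_matrix=None):
    """Sex-by-predictor interaction with a family-level random intercept.

    Fits ``outcome ~ sex + predictor + sex:predictor + covariates`` with a
    random intercept per family by maximum likelihood.  The predictor is
    centered internally.  If the family variance estimate collapses to zero
    the model degrades to OLS (with a logged notice) — the fixed-effect
    estimates coincide in that limit.

    Returns (coefficient, p) for the interaction term.
    """
    y = np.asarray(outcome, dtype=float)
    sexarr = np.asarray(sex)
    levels = np.unique(sexarr)
    if levels.size != 2:
        raise ValueError("sex must have exactly two levels")
    s = (sexarr == levels[1]).astype(float)
    x = np.asarray(predictor, dtype=float)
    x = x - x.mean()
    fam = np.asarray(family_ids)
    if np.unique(fam).size < 2:
        raise ValueError("all subjects share one family; random intercept unidentified")
    Z, names = _as_design(covariate_matrix)
    cols = {"sex": s, "predictor": x, "interaction": s * x}
    for j, nm in enumerate(names):
        cols[nm] = Z[:, j]
    exog = pd.DataFrame(cols)
    exog.insert(0, "const", 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=fam)
        try:
            fit = model.fit(reml=False, method="lbfgs")
            var_fam = float(fit.cov_re.iloc[0, 0])
        except Exception:
            fit, var_fam = None, 0.0
    if fit is None or var_fam < 1e-10 or not np.isfinite(fit.pvalues["interaction"]):
        warnings.warn("family variance ~0; falling back to OLS for the interaction test")
        ols = sm.OLS(y, exog).fit()
        return float(ols.params["interaction"]), float(ols.pvalues["interaction"])
    return float(fit.params["interaction"]), float(fit.pvalues["interaction"])


def diagnosis_rate(table: pd.DataFrame, cutoff: float,
                   score_col: str = "adhd_t", sex_col: str = "sex") -> dict:
    """Per-sex count and percentage of subjects with score >= cutoff."""
    out = {}
    for sx, sub in table.groupby(sex_col, observed=True):
        n = len(sub)
        count = int((sub[score_col] >= cutoff).sum())
        out[str(sx)] = {"n": n, "count": count,
                        "percent": 100.0 * count / n if n else 0.0}
    return out


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
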