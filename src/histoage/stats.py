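"""Bias-corrected age acceleration and cohort association statistics.

Age-estimation models regress toward the training-set mean, so the raw
difference ``Y' - Y`` is itself age-dependent. Acceleration is therefore
defined as the residual of the OLS regression of predicted age on
chronological age — by construction mean-zero and uncorrelated with
chronological age.

Association analyses mirror conventional neuropathology reporting:
univariate two-sample t (binary), one-way ANOVA (multi-category),
Pearson (continuous) and Spearman (ordinal) tests, plus adjusted models
(logistic for binary outcomes, OLS otherwise) with sex and chronological
age as nuisance covariates. Acceleration is standardised to unit
variance inside adjusted models, so odds ratios are per SD of
acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["AssociationResult", "compute_acceleration", "associate_univariate",
           "associate_adjusted", "label_cognitive_impairment", "clock_comparison"]

CDR_IMPAIRED = 0.5
MMSE_IMPAIRED = 24


@dataclass
class AssociationResult:
    variable: str
    test: str                # "t" | "anova_f" | "pearson_r" | "spearman_rho" | "logistic_or" | "ols_beta"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    flag: str | None = None  # e.g. perfect-separation warning

    def as_dict(self) -> dict:
        return {"variable": self.variable, "test": self.test,
                "estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p": self.p_value, "n": self.n,
                "flag": self.flag}


def compute_acceleration(predictions: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of predicted age on chronological age.

    ``predictions`` needs columns ``slide_id`` (or ``id``), ``age`` and
    ``y_hat``. Returns the table with fitted values and an ``accel``
    column; residuals are exactly orthogonal to age and the intercept.
    """
    df = predictions.copy()
    if len(df) < 3:
        raise ValueError("need at least 3 subjects for bias correction")
    if np.ptp(df["age"].to_numpy(dtype=float)) == 0:
        raise ValueError("chronological ages are constant; regression undefined")
    x = sm.add_constant(df["age"].to_numpy(dtype=float))
    fit = sm.OLS(df["y_hat"].to_numpy(dtype=float), x).fit()
    df["fitted"] = fit.fittedvalues
    df["accel"] = fit.resid
    return df


def _complete(*cols: np.ndarray) -> tuple[np.ndarray, ...]:
    stacked = np.column_stack(cols).astype(float)
    keep = ~np.isnan(stacked).any(axis=1)
    return tuple(stacked[keep, i] for i in range(stacked.shape[1]))


def associate_univariate(accel: np.ndarray, covariate: np.ndarray,
                         kind: str, name: str = "", welch: bool = False) -> AssociationResult:
    """Univariate association between acceleration and one covariate.

    ``kind``: "binary" (two-sample t), "categorical" (one-way ANOVA F),
    "continuous" (Pearson r), "ordinal" (Spearman rho). Complete-case
    per variable; n reported.
    """
    a, c = _complete(np.asarray(accel, float), np.asarray(covariate, float))
    n = len(a)
    if kind == "binary":
        levels = np.unique(c)
        if len(levels) != 2:
            raise ValueError(f"{name or 'covariate'}: binary covariate needs 2 levels")
        g0, g1 = a[c == levels[0]], a[c == levels[1]]
        if min(len(g0), len(g1)) == 0:
            raise ValueError(f"{name or 'covariate'}: empty group")
        if np.array_equal(np.sort(g0), np.sort(g1)):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(g1, g0, equal_var=not welch)
        return AssociationResult(name, "t", float(t), np.nan, np.nan, float(p), n)
    if kind == "categorical":
        groups = [a[c == lv] for lv in np.unique(c)]
        if any(len(g) == 0 for g in groups):
            raise ValueError(f"{name or 'covariate'}: empty group")
        f, p = sps.f_oneway(*groups)
        return AssociationResult(name, "anova_f", float(f), np.nan, np.nan, float(p), n)
    if kind == "continuous":
        r, p = sps.pearsonr(a, c)
        lo, hi = sps.pearsonr(a, c).confidence_interval()
        return AssociationResult(name, "pearson_r", float(r), float(lo), float(hi),
                                 float(p), n)
    if kind == "ordinal":
        rho, p = sps.spearmanr(a, c)
        return AssociationResult(name, "spearman_rho", float(rho), np.nan, np.nan,
                                 float(p), n)
    raise ValueError(f"unknown covariate kind {kind!r}")


def associate_adjusted(
    accel: np.ndarray,
    outcome: np.ndarray,
    sex: np.ndarray,
    age: np.ndarray,
    binary: bool | None = None,
    name: str = "",
    standardize: bool = True,
) -> AssociationResult:
    """Adjusted association: outcome ~ acceleration + sex + age.

    Binary outcomes use maximum-likelihood logistic regression and
    report an odds ratio per SD of acceleration with a Wald 95% CI;
    other outcomes use OLS and report beta. Perfect separation is
    flagged rather than silently failing.
    """
    a, o, s, y = _complete(np.asarray(accel, float), np.asarray(outcome, float),
                           np.asarray(sex, float), np.asarray(age, float))
    n = len(a)
    if n < 4:
        raise ValueError("too few complete cases for an adjusted model")
    if binary is None:
        binary = len(np.unique(o)) == 2
    if standardize:
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("acceleration is constant")
        a = a / sd
    x = sm.add_constant(np.column_stack([a, s, y]))
    if binary:
        o = (o == np.max(o)).astype(float) if set(np.unique(o)) != {0.0, 1.0} else o
        flag = None
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(o, x).fit(disp=0, maxiter=200)
            beta = fit.params[1]
            se = fit.bse[1]
            if not np.isfinite(se) or se > 50:
                flag = "possible perfect separation; CI unbounded"
        except Exception:
            return AssociationResult(name, "logistic_or", np.inf, 0.0, np.inf, np.nan,
                                     n, flag="perfect separation")
        lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
        return AssociationResult(name, "logistic_or", float(np.exp(beta)),
                                 float(np.exp(lo)), float(np.exp(hi)),
                                 float(fit.pvalues[1]), n, flag=flag)
    fit = sm.OLS(o, x).fit()
    lo, hi = fit.conf_int()[1]
    return AssociationResult(name, "ols_beta", float(fit.params[1]), float(lo),
                             float(hi), float(fit.pvalues[1]), n)


def label_cognitive_impairment(record: pd.Series | dict) -> float:
    """Composite impairment label: CDR >= 0.5, or MMSE <= 24, or clinical diagnosis.

    Returns 1.0 (impaired), 0.0 (assessed and unimpaired) or NaN when
    none of the three fields is available.
    """
    cdr = record.get("cdr")
    mmse = record.get("mmse")
    dx = record.get("dx_impairment")
    present = [v for v in (cdr, mmse, dx) if v is not None and not pd.isna(v)]
    if not present:
        return float("nan")
    if cdr is not None and not pd.isna(cdr) and cdr >= CDR_IMPAIRED:
        return 1.0
    if mmse is not None and not pd.isna(mmse) and mmse <= MMSE_IMPAIRED:
        return 1.0
    if dx is not None and not pd.isna(dx) and bool(dx):
        return 1.0
    return 0.0


def clock_comparison(table: pd.DataFrame, clock_columns: list[str],
                     age_col: str = "age", histo_col: str = "accel"
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-correlate histology-based and clock-based accelerations.

    Each clock-age column is bias-corrected the same way (residual of
    clock age on chronological age, complete cases per clock). Returns
    (r matrix, p matrix, per-clock acceleration table). Pairs with < 3
    complete cases are NaN.
    """
    accels = pd.DataFrame(index=table.index)
    accels["histo"] = table[histo_col]
    age = table[age_col].to_numpy(dtype=float)
    for col in clock_columns:
        vals = table[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals) & ~np.isnan(age)
        res = np.full(len(table), np.nan)
        if ok.sum() >= 3 and np.ptp(age[ok]) > 0:
            x = sm.add_constant(age[ok])
            res[ok] = sm.OLS(vals[ok], x).fit().resid
        accels[col] = res
    names = list(accels.columns)
    k = len(names)
    r_mat = pd.DataFrame(np.eye(k), index=names, columns=names)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = _complete(accels[names[i]].to_numpy(), accels[names[j]].to_numpy())
            if len(a) < 3:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(a, b)
            r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
    return r_mat, p_mat, accels
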