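"""Shared statistical primitives: t-tests, BH-FDR, OLS and logistic fits.

These are thin, fast wrappers with explicit result containers so that every
analysis stage reports coefficients, standard errors, effect sizes and
FDR-adjusted q-values in the same shape.  OLS uses the closed-form normal
equations (the per-subject regressions here are small and run thousands of
times in calibration loops); the logistic fit delegates to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """One-sample or paired t-test result with Cohen's d (mean/SD)."""

    statistic: float
    df: int
    p: float
    d: float
    mean: float
    sem: float
    flagged: bool = False
    note: str = ""


@dataclass
class RegressionResult:
    """Per-subject regression fit.

    coefficients/se are indexed by predictor name; ``model`` tags the link
    (``ols_logrt`` or ``logistic_accuracy``).
    """

    coefficients: pd.Series
    se: pd.Series
    model: str
    n: int
    resid_var: float = np.nan
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.coefficients.index.duplicated().any():
            raise ValueError("duplicate predictor names")


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test against ``mu0`` with Cohen's d = mean/SD."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("one_sample_t requires at least 2 values")
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return TestResult(np.nan, n - 1, np.nan, np.nan, mean, 0.0,
                          flagged=True, note="zero variance")
    t, p = sps.ttest_1samp(x, mu0)
    return TestResult(float(t), n - 1, float(p), float((mean - mu0) / sd),
                      float(mean), float(sd / np.sqrt(n)))


def paired_t(a, b) -> TestResult:
    """Two-sided paired t-test; effect size is mean/SD of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired_t requires equal-length inputs")
    return one_sample_t(a - b, 0.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ols_fit(y, X, names, model: str = "ols_logrt") -> RegressionResult:
    """Ordinary least squares via the normal equations.

    Parameters
    ----------
    y : (n,) outcome
    X : (n, p) design matrix (caller includes the constant column)
    names : sequence of p predictor names
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer observations ({n}) than predictors ({p})")
    if len(names) != p:
        raise ValueError("names must match design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient design (rank {rank} < {p} columns)")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = n - p
    s2 = float(resid @ resid / dof) if dof > 0 else np.nan
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * s2)
    return RegressionResult(
        coefficients=pd.Series(beta, index=list(names)),
        se=pd.Series(se, index=list(names)),
        model=model, n=n, resid_var=s2,
    )


def logistic_fit(y, X, names, model: str = "logistic_accuracy") -> RegressionResult:
    """Maximum-likelihood logistic regression (statsmodels Logit).

    Perfect separation or non-convergence is reported via ``converged=False``
    rather than raised, so group-level code can drop the subject with a
    warning instead of aborting a whole simulation.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer observations ({n}) than predictors ({p})")
    converged = True
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            beta, se = fit.params, fit.bse
        except Exception as exc:  # separation / singular Hessian
            converged = False
            note = f"logistic fit failed: {exc}"
            beta = np.full(p, np.nan)
            se = np.full(p, np.nan)
    if converged and not np.all(np.isfinite(se)):
        converged = False
        note = note or "non-finite standard errors (possible separation)"
    return RegressionResult(
        coefficients=pd.Series(np.asarray(beta), index=list(names)),
        se=pd.Series(np.asarray(se), index=list(names)),
        model=model, n=n, converged=converged, note=note,
    )


@dataclass
class GroupStats:
    """Group-level summary over per-subject coefficients.

    One row per predictor: mean, SEM, t (df = n-1), two-sided p, Cohen's d,
    and BH-FDR q computed within the declared family (all rows).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_subject_coefficients(cls, coefs: pd.DataFrame,
                                  fdr_family=None) -> "GroupStats":
        """``coefs``: subjects x predictors. ``fdr_family``: predictor names
        included in the FDR correction (default: all)."""
        rows = []
        for name in coefs.columns:
            vals = coefs[name].dropna().to_numpy()
            res = one_sample_t(vals)
            rows.append(dict(predictor=name, mean=res.mean, sem=res.sem,
                             t=res.statistic, df=res.df, p=res.p, d=res.d,
                             n=vals.size, flagged=res.flagged))
        tab = pd.DataFrame(rows).set_index("predictor")
        family = list(fdr_family) if fdr_family is not None else list(tab.index)
        tab["q"] = np.nan
        ok = tab.loc[family, "p"].notna()
        fam = [f for f in family if ok[f]]
        if fam:
            tab.loc[fam, "q"] = bh_fdr(tab.loc[fam, "p"].to_numpy())
        return cls(table=tab)
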