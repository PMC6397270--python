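"""MeHg/THg fraction estimation by filtered zero-intercept regression.

Methylmercury is assayed on a subset of topcoat samples. The fraction of
total mercury present as methylmercury is the slope beta of the no-intercept
model MeHg = beta * THg; samples whose MeHg/THg ratio exceeds 110% are
removed first as analytical error (MeHg cannot truly exceed THg; modest
overshoot reflects the two assays' independent errors). Four residual
diagnostics accompany the fit: a RESET-type linearity test, a Breusch-Pagan
score test for non-constant variance, Shapiro-Wilk normality, and
Durbin-Watson serial correlation with residuals taken in THg order (the
samples carry no time index, so the ordering is by the regressor —
deterministic and disclosed).

R^2 follows the no-intercept convention (uncentered total sum of squares),
stated explicitly because published R^2 values for zero-intercept fits are
not comparable with centred ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan, linear_reset
from statsmodels.stats.stattools import durbin_watson

from .pelt_model import SamplePoint, ValidationError


class FitError(ValueError):
    pass


RATIO_CUTOFF = 1.10


@dataclass
class Diagnostic:
    statistic: float
    p_value: float
    note: str = ""


@dataclass
class RatioFit:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    r_squared: float           # uncentered convention
    n_used: int
    n_removed_by_filter: int
    diagnostics: dict[str, Diagnostic] = field(default_factory=dict)


def filter_ratio(points: list[SamplePoint],
                 cutoff: float = RATIO_CUTOFF) -> tuple[list, list]:
    """Split points into (kept, removed) by the MeHg/THg ratio.

    A point is removed iff mehg/thg is strictly greater than the cutoff
    (default 110%); a ratio of exactly 110% is kept. Points without a MeHg
    value are ignored (neither kept nor removed).
    """
    import warnings

    kept, removed = [], []
    for p in points:
        if p.mehg is None:
            continue
        if p.thg == 0:
            raise ValidationError(
                f"thg = 0 at cell ({p.row}, {p.col}): ratio undefined")
        (removed if p.mehg / p.thg > cutoff else kept).append(p)
    if not kept and not removed:
        warnings.warn("no MeHg values present", RuntimeWarning, stacklevel=2)
    return kept, removed


def zero_intercept_fit(x, y, alpha: float = 0.05,
                       n_removed: int = 0) -> RatioFit:
    """Least-squares slope of y = beta * x through the origin.

    beta = sum(xy) / sum(x^2); se and CI use n - 1 residual df; R^2 is
    computed on the uncentered total sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise FitError("need >= 3 points after filtering")
    sxx = float(np.sum(x ** 2))
    if sxx == 0:
        raise FitError("sum of squares of x is zero")
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    dof = n - 1
    sigma2 = float(np.sum(resid ** 2) / dof)
    se = float(np.sqrt(sigma2 / sxx))
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    tss = float(np.sum(y ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else np.nan
    return RatioFit(beta=beta, se=se,
                    ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
                    r_squared=r2, n_used=n, n_removed_by_filter=n_removed)


def regression_diagnostics(residuals, fitted, x) -> dict[str, Diagnostic]:
    """The four assumption checks on a fitted no-intercept model.

    linearity: RESET test adding powers 2-3 of the fitted values;
    homoscedasticity: Breusch-Pagan score test of squared residuals on x;
    normality: Shapiro-Wilk on the residuals;
    autocorrelation: Durbin-Watson with residuals in ascending-x order
    (statistic only, plus a verdict: < 1.5 positive, > 2.5 negative,
    otherwise none).
    """
    residuals = np.asarray(residuals, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(residuals)
    if n < 8:
        raise FitError(
            "need >= 8 points: RESET, Breusch-Pagan, Shapiro-Wilk and "
            "Durbin-Watson are not all defined below that")
    out: dict[str, Diagnostic] = {}

    # RESET: refit including fitted^2, fitted^3 and F-test the added terms
    model = sm.OLS(fitted + residuals, x[:, None]).fit()
    reset = linear_reset(model, power=[2, 3], test_type="fitted", use_f=True)
    out["linearity"] = Diagnostic(float(reset.fvalue), float(reset.pvalue),
                                  "RESET on powers 2-3 of fitted values")

    exog = sm.add_constant(x)
    lm_stat, lm_p, _, _ = het_breuschpagan(residuals, exog)
    out["homoscedasticity"] = Diagnostic(float(lm_stat), float(lm_p),
                                         "Breusch-Pagan score test")

    w, p = stats.shapiro(residuals)
    out["normality"] = Diagnostic(float(w), float(p), "Shapiro-Wilk")

    order = np.argsort(x, kind="stable")
    dw = float(durbin_watson(residuals[order]))
    verdict = ("positive" if dw < 1.5 else
               "negative" if dw > 2.5 else "none")
    out["autocorrelation"] = Diagnostic(
        dw, np.nan, f"Durbin-Watson in x order; verdict: {verdict}")
    return out


def fit_mehg_ratio(points: list[SamplePoint], alpha: float = 0.05,
                   with_diagnostics: bool = True) -> RatioFit:
    """filter_ratio -> zero_intercept_fit -> diagnostics, end to end."""
    kept, removed = filter_ratio(points)
    x = np.array([p.thg for p in kept])
    y = np.array([p.mehg for p in kept])
    fit = zero_intercept_fit(x, y, alpha=alpha, n_removed=len(removed))
    if with_diagnostics and len(kept) >= 8:
        resid = y - fit.beta * x
        fit.diagnostics = regression_diagnostics(resid, fit.beta * x, x)
    return fit
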