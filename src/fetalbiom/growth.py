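"""Growth-curve analysis of biometric measurements against gestational age.

Provides the reference-table and regression layer: per-GA-week summary
statistics (mean, SD, quartiles with small-week exclusion), polynomial
ordinary-least-squares growth curves with data-driven degree selection,
t-based confidence and prediction bands, a paired bilateral comparison of
the two atrial diameters, and the (LAD+RAD)/CBPD ratio index that captures
how ventricular width stays constant while the brain grows.

Degree selection compares OLS fits of the candidate degrees (default
{1, 2, 3}) by BIC with ties broken toward the lower degree.  Plain R² is
monotone in degree and adjusted R² prefers a spurious extra term whenever
its F statistic exceeds 1 (probability ≈ 0.32 under the null), so neither
yields a stable "quadratic is best" verdict on curved data; BIC's stronger
complexity penalty does.  R² and adjusted R² are reported on the fit.
Gestational age is centered and scaled internally before fitting to avoid
ill-conditioned Vandermonde matrices; coefficients are reported
back-transformed to the natural GA scale (ascending powers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial import Polynomial
from scipy import stats

from .errors import ConstantInputError

__all__ = [
    "GrowthTable",
    "PolyFit",
    "PredictionBand",
    "BilateralResult",
    "RatioIndexResult",
    "summarize_by_ga",
    "fit_growth",
    "prediction_band",
    "bilateral_compare",
    "ratio_index",
]

DEFAULT_DEGREES = (1, 2, 3)


@dataclass(frozen=True)
class GrowthTable:
    """Per-GA-week reference statistics.

    ``table`` columns: ga_week, n, mean_mm, sd_mm, q1_mm, median_mm, q3_mm,
    excluded (True for weeks whose n falls below the reporting cutoff).
    Quartiles use linear interpolation on the sorted sample (the inclusive
    convention: quartiles of {1,2,3,4} are 1.75 and 3.25).
    """

    table: pd.DataFrame
    min_n: int

    @property
    def included(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]].reset_index(drop=True)

    @property
    def total_n(self) -> int:
        return int(self.table["n"].sum())


@dataclass
class PolyFit:
    """An OLS polynomial fit of measurement on gestational age.

    ``coefficients`` are ascending powers on the natural GA scale;
    ``residual_sd`` is sqrt(SSE / (n − degree − 1)).  The fitted design is
    retained internally so prediction bands can be derived from the fit.
    """

    degree: int
    coefficients: np.ndarray
    r_squared: float
    adj_r_squared: float
    residual_sd: float
    n: int
    _result: object = field(repr=False, default=None)
    _ga_mean: float = field(repr=False, default=0.0)
    _ga_scale: float = field(repr=False, default=1.0)
    _ga_range: tuple[float, float] = field(repr=False, default=(0.0, 0.0))

    def predict(self, ga_weeks) -> np.ndarray:
        ga = np.asarray(ga_weeks, dtype=float)
        return Polynomial(self.coefficients)(ga)


@dataclass(frozen=True)
class PredictionBand:
    """Mean-confidence and single-observation prediction intervals on a grid.

    ``extrapolated`` flags grid points outside the fitted GA range (allowed,
    but marked).  Pointwise, pi_low <= ci_low <= fit <= ci_high <= pi_high.
    """

    ga_grid: np.ndarray
    fit_mm: np.ndarray
    ci_low_mm: np.ndarray
    ci_high_mm: np.ndarray
    pi_low_mm: np.ndarray
    pi_high_mm: np.ndarray
    level: float
    extrapolated: np.ndarray


@dataclass(frozen=True)
class BilateralResult:
    """Paired two-sided t-test of LAD − RAD."""

    mean_diff_mm: float
    t_statistic: float
    p_value: float
    degenerate: bool = False  # zero-variance differences with nonzero mean


@dataclass(frozen=True)
class RatioIndexResult:
    """The (LAD+RAD)/CBPD index, its GA correlation and growth fit."""

    index: np.ndarray
    pearson_r: float
    p_value: float
    fit: PolyFit


def summarize_by_ga(values_mm, ga_weeks, min_n: int = 5) -> GrowthTable:
    """Group measurements by floor(GA week) and summarize each week.

    Weeks with fewer than ``min_n`` cases are flagged ``excluded`` rather
    than dropped, so total n is conserved across included + excluded weeks.
    """
    values = np.asarray(values_mm, dtype=float)
    ga = np.asarray(ga_weeks, dtype=float)
    if len(values) == 0 or len(values) != len(ga):
        raise ValueError("values and ga_weeks must be equal-length and non-empty")
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    week = np.floor(ga).astype(int)
    rows = []
    for wk in np.unique(week):
        v = np.sort(values[week == wk])
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
        rows.append(
            {
                "ga_week": int(wk),
                "n": len(v),
                "mean_mm": float(v.mean()),
                "sd_mm": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "q1_mm": float(q1),
                "median_mm": float(med),
                "q3_mm": float(q3),
                "excluded": len(v) < min_n,
            }
        )
    return GrowthTable(table=pd.DataFrame(rows), min_n=int(min_n))


def _design(g: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(g, degree + 1, increasing=True)


def fit_growth(
    values_mm, ga_weeks, candidate_degrees=DEFAULT_DEGREES
) -> PolyFit:
    """OLS polynomial fit with BIC degree selection (ties → lower degree)."""
    y = np.asarray(values_mm, dtype=float)
    ga = np.asarray(ga_weeks, dtype=float)
    degrees = sorted(int(d) for d in candidate_degrees)
    if len(degrees) == 0 or degrees[0] < 1:
        raise ValueError("candidate degrees must be integers >= 1")
    if len(y) != len(ga):
        raise ValueError("values and ga_weeks must have equal length")
    if len(y) <= max(degrees) + 1:
        raise ValueError(
            f"need n > max degree + 1 = {max(degrees) + 1}, got n = {len(y)}"
        )
    ga_sd = ga.std()
    if ga_sd == 0:
        raise ValueError("all GA values identical: design is rank deficient")
    ga_mean = ga.mean()
    g = (ga - ga_mean) / ga_sd

    best = None
    for d in degrees:
        res = sm.OLS(y, _design(g, d)).fit()
        sse = float(res.ssr)
        n = len(y)
        if sse <= max(1e-12 * float(np.sum((y - y.mean()) ** 2)), 1e-300):
            bic = -np.inf  # perfect fit: tie broken toward the lower degree
        else:
            bic = n * np.log(sse / n) + (d + 2) * np.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, d, res)
    _, degree, res = best

    # back-transform coefficients from the standardized to the natural scale
    p_scaled = Polynomial(np.asarray(res.params))
    p_natural = p_scaled(Polynomial([-ga_mean / ga_sd, 1.0 / ga_sd]))
    coeffs = np.zeros(degree + 1)
    coeffs[: len(p_natural.coef)] = p_natural.coef

    dof = len(y) - degree - 1
    return PolyFit(
        degree=degree,
        coefficients=coeffs,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        residual_sd=float(np.sqrt(res.ssr / dof)) if dof > 0 else 0.0,
        n=len(y),
        _result=res,
        _ga_mean=float(ga_mean),
        _ga_scale=float(ga_sd),
        _ga_range=(float(ga.min()), float(ga.max())),
    )


def prediction_band(fit: PolyFit, ga_grid, level: float = 0.95) -> PredictionBand:
    """t-based OLS confidence and prediction intervals along a GA grid.

    The confidence interval covers the mean response, the prediction
    interval a new single observation; grid points outside the fitted GA
    range are flagged ``extrapolated`` rather than rejected.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if fit._result is None:
        raise ValueError("PolyFit carries no fitted design; refit with fit_growth")
    grid = np.asarray(ga_grid, dtype=float)
    g = (grid - fit._ga_mean) / fit._ga_scale
    pred = fit._result.get_prediction(_design(g, fit.degree))
    alpha = 1.0 - level
    ci = pred.conf_int(obs=False, alpha=alpha)
    pi = pred.conf_int(obs=True, alpha=alpha)
    lo, hi = fit._ga_range
    return PredictionBand(
        ga_grid=grid,
        fit_mm=np.asarray(pred.predicted_mean),
        ci_low_mm=ci[:, 0],
        ci_high_mm=ci[:, 1],
        pi_low_mm=pi[:, 0],
        pi_high_mm=pi[:, 1],
        level=float(level),
        extrapolated=(grid < lo) | (grid > hi),
    )


def bilateral_compare(lad_mm, rad_mm) -> BilateralResult:
    """Paired two-sided t-test on LAD − RAD."""
    lad = np.asarray(lad_mm, dtype=float)
    rad = np.asarray(rad_mm, dtype=float)
    if len(lad) != len(rad) or len(lad) < 3:
        raise ValueError("bilateral comparison needs paired sequences of length >= 3")
    d = lad - rad
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return BilateralResult(0.0, 0.0, 1.0)
        return BilateralResult(mean, float(np.sign(mean)) * np.inf, 0.0, degenerate=True)
    t = mean / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return BilateralResult(mean, float(t), float(p))


def ratio_index(lad_mm, rad_mm, cbpd_mm, ga_weeks) -> RatioIndexResult:
    """(LAD+RAD)/CBPD per case, its Pearson r with GA, and a growth fit.

    As the cerebrum grows while atrial width stays constant, the index
    declines with GA (negative correlation).
    """
    lad = np.asarray(lad_mm, dtype=float)
    rad = np.asarray(rad_mm, dtype=float)
    cbpd = np.asarray(cbpd_mm, dtype=float)
    ga = np.asarray(ga_weeks, dtype=float)
    if not (len(lad) == len(rad) == len(cbpd) == len(ga)):
        raise ValueError("all sequences must have equal length")
    if np.any(cbpd <= 0):
        raise ValueError("cbpd values must be positive")
    index = (lad + rad) / cbpd
    if np.ptp(index) == 0 or np.ptp(ga) == 0:
        raise ConstantInputError("ratio index correlation undefined for constant input")
    r, p = stats.pearsonr(index, ga)
    fit = fit_growth(index, ga)
    return RatioIndexResult(index=index, pearson_r=float(r), p_value=float(p), fit=fit)
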