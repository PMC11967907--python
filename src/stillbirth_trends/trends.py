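"""Trend battery for national stillbirth-rate series.

Three procedures, all operating on a :class:`~stillbirth_trends.tables.RateSeries`:

* :func:`mk_test` — Mann–Kendall test for monotonic trend.  The variance of
  the S statistic uses the tie-corrected formula and, optionally, the
  Hamed–Rao variance-inflation correction for serial autocorrelation,
  computed on the ranks of the Sen-detrended series with per-lag
  significance screening at the 5% level.

* :func:`fit_linear` / :func:`fit_segmented` — OLS annual-change slopes.
  The segmented fit tests for a single slope change with a score-type test
  of the added hinge covariate maximised over a grid of candidate knots,
  the grid-maximum p-value adjusted with the Davies upper bound.  When the
  test is significant the continuous one-knot broken-line model is fitted
  by profile search over the knot.

* :func:`robust_anomaly` — robust standardized residuals for designated
  years (pandemic surveillance): a Theil–Sen trend is fitted to the series
  excluding the target years, and each target's residual is scaled by
  1.4826 x MAD of the reference residuals.  Flagging is one-sided (only
  unusually *high* rates flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .tables import RateSeries

__all__ = [
    "MKResult",
    "TrendFit",
    "AnomalyResult",
    "mk_test",
    "fit_linear",
    "fit_segmented",
    "robust_anomaly",
    "mk_s_statistic",
    "significance_stars",
]


# --------------------------------------------------------------------------
# Mann–Kendall
# --------------------------------------------------------------------------


@dataclass
class MKResult:
    """Mann–Kendall test outcome.

    S
        Signed count of concordant minus discordant pairs.
    var_s
        Variance of S after tie correction and (optionally) autocorrelation
        inflation.
    z, p
        Continuity-corrected standard normal statistic and two-sided p-value.
    n_eff_ratio
        Variance inflation factor n/n* (1 when no correction applies).
    """

    S: int
    var_s: float
    z: float
    p: float
    n_eff_ratio: float

    @property
    def trend(self) -> str:
        if self.p >= 0.05 or self.S == 0:
            return "no trend"
        return "increasing" if self.S > 0 else "decreasing"


def mk_s_statistic(x: np.ndarray) -> int:
    """S = sum over i<j of sign(x_j - x_i)."""
    x = np.asarray(x, dtype=float)
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def _tie_corrected_var(x: np.ndarray) -> float:
    n = len(x)
    var = n * (n - 1) * (2 * n + 5) / 18.0
    _, counts = np.unique(x, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5) / 18.0
    return var


def _rank_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation function (denominator n convention), lags 0..max_lag."""
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.zeros(max_lag + 1)
    full = np.correlate(x, x, mode="full")
    acf = full[len(x) - 1 : len(x) + max_lag] / denom
    return acf


def _hamed_rao_factor(x: np.ndarray, screen_alpha: float = 0.10) -> float:
    """Variance inflation n/n* from the lag autocorrelations of the ranks of
    the Sen-detrended series; only lags significant at ``screen_alpha`` enter.

    The factor is floored at 1: the correction is a variance *inflation*
    guarding against positive serial dependence, and estimated negative
    autocorrelations on short series must not shrink Var(S) below its iid
    value (which would inflate the test's size).
    """
    n = len(x)
    t = np.arange(n, dtype=float)
    slope = stats.theilslopes(x, t).slope
    ranks = stats.rankdata(x - slope * t)
    acf = _rank_acf(ranks, max_lag=n - 1)
    bound = stats.norm.ppf(1.0 - screen_alpha / 2.0) / np.sqrt(n)

    s = 0.0
    for lag in range(1, n - 2):  # factor (n-i)(n-i-1)(n-i-2) vanishes beyond
        if abs(acf[lag]) > bound:
            s += (n - lag) * (n - lag - 1) * (n - lag - 2) * acf[lag]
    factor = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * s
    return max(factor, 1.0)


def mk_test(series: RateSeries | np.ndarray, correct_autocorr: bool = True) -> MKResult:
    """Mann–Kendall test for a monotonic trend in an annual rate series.

    With ``correct_autocorr`` the tie-corrected Var(S) is multiplied by the
    Hamed–Rao rank-based inflation factor using only lags whose
    autocorrelation is significant at 5%; a white-noise series therefore
    keeps factor 1 in expectation.  A constant series returns S = 0, z = 0,
    p = 1 rather than an error.
    """
    x = series.rates if isinstance(series, RateSeries) else np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"Mann–Kendall requires n >= 4, got {n}")

    s = mk_s_statistic(x)
    if np.all(x == x[0]):
        return MKResult(S=0, var_s=0.0, z=0.0, p=1.0, n_eff_ratio=1.0)

    var_s = _tie_corrected_var(x)
    ratio = _hamed_rao_factor(x) if correct_autocorr else 1.0
    var_s *= ratio

    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return MKResult(S=s, var_s=float(var_s), z=float(z), p=float(p), n_eff_ratio=float(ratio))


def significance_stars(p: float) -> str:
    """Conventional star notation: * p<.05, ** p<.01, *** p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# Linear and segmented regression
# --------------------------------------------------------------------------


@dataclass
class TrendFit:
    """Fitted annual trend, linear or one-knot broken line.

    slopes
        (slope,) for a linear fit; (slope_before, slope_after) when a
        breakpoint was detected.  Units: rate change per 1000 per year.
    breakpoint_year
        Real-valued knot location, present iff kind == 'segmented'.
    score_test_p
        Davies-adjusted p-value for the slope-change score test.
    ci
        Per-year mean prediction with 95% confidence limits
        (columns year, fit, lo, hi).
    """

    kind: str
    slopes: tuple[float, ...]
    intercept: float
    breakpoint_year: float | None
    score_test_p: float | None
    ci: pd.DataFrame = field(repr=False, default=None)

    def predict(self, year: float | np.ndarray) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        y = self.intercept + self.slopes[0] * year
        if self.kind == "segmented":
            y = y + (self.slopes[1] - self.slopes[0]) * np.clip(
                year - self.breakpoint_year, 0.0, None
            )
        return y


def _ols_ci(x: np.ndarray, y: np.ndarray, design: np.ndarray, level: float = 0.95):
    """Mean-prediction CI for an OLS fit with design matrix ``design``."""
    n, k = design.shape
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    xtx_inv = np.linalg.pinv(design.T @ design)
    se_fit = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", design, xtx_inv, design), 0) * sigma2)
    tq = stats.t.ppf(0.5 + level / 2.0, dof) if dof > 0 else 0.0
    fit = design @ beta
    return beta, resid, sigma2, pd.DataFrame(
        {"year": x, "fit": fit, "lo": fit - tq * se_fit, "hi": fit + tq * se_fit}
    )


def fit_linear(series: RateSeries) -> TrendFit:
    """OLS line through the annual rates; slope per calendar year."""
    x = series.years.astype(float)
    y = series.rates
    if len(x) < 3:
        raise InsufficientDataError(f"linear fit requires n >= 3, got {len(x)}")
    design = np.column_stack([np.ones_like(x), x])
    beta, _, _, ci = _ols_ci(x, y, design)
    return TrendFit(
        kind="linear",
        slopes=(float(beta[1]),),
        intercept=float(beta[0]),
        breakpoint_year=None,
        score_test_p=None,
        ci=ci,
    )


def _knot_grid(x: np.ndarray, min_segment: int, step: float = 0.1) -> np.ndarray:
    """Candidate knots at ``step`` resolution between the min_segment-th and
    (n - min_segment)-th observations (inclusive)."""
    lo = x[min_segment - 1]
    hi = x[len(x) - min_segment]
    if hi < lo:
        return np.array([])
    return np.round(np.arange(lo, hi + step / 2.0, step), 10)


def _score_process(x: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """t-type score statistic of the added hinge covariate at each knot."""
    n = len(x)
    design0 = np.column_stack([np.ones_like(x), x])
    h0 = design0 @ np.linalg.pinv(design0.T @ design0) @ design0.T
    r = y - h0 @ y
    rss0 = float(r @ r)
    if rss0 <= 1e-12 * max(1.0, float(y @ y)):
        return np.zeros(len(grid))  # perfect line: no evidence of slope change
    sigma2 = rss0 / (n - 2)

    hinges = np.clip(x[None, :] - grid[:, None], 0.0, None)  # (G, n)
    hp = hinges - hinges @ h0.T  # projected out intercept+slope
    norms = np.sqrt(np.einsum("ij,ij->i", hp, hp))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (hp @ r) / (np.sqrt(sigma2) * norms)
    z[~np.isfinite(z)] = 0.0
    return z


def _davies_p(z: np.ndarray, dof: int) -> float:
    """Upper bound on the p-value of max |Z(knot)| over the grid (Davies)."""
    m = float(np.max(np.abs(z)))
    if m == 0.0:
        return 1.0
    p_naive = 2.0 * stats.t.sf(m, dof)
    total_variation = float(np.sum(np.abs(np.diff(z))))
    correction = total_variation * np.exp(-(m**2) / 2.0) / np.sqrt(8.0 * np.pi)
    return float(min(1.0, p_naive + correction))


def fit_segmented(
    series: RateSeries,
    alpha: float = 0.05,
    min_segment: int = 3,
    grid_step: float = 0.1,
) -> TrendFit:
    """One-knot broken-line fit, reported only when the slope-change score
    test is significant; otherwise the plain linear fit is returned.

    The knot is located by profile least squares over the candidate grid and
    refined by bounded minimisation between the neighbouring grid points.
    """
    x = series.years.astype(float)
    y = series.rates
    n = len(x)
    if n < 2 * min_segment + 1:
        raise InsufficientDataError(
            f"segmented fit requires n >= {2 * min_segment + 1}, got {n}"
        )

    grid = _knot_grid(x, min_segment, grid_step)
    if grid.size == 0:
        return fit_linear(series)

    z = _score_process(x, y, grid)
    p = _davies_p(z, dof=n - 3)
    if p >= alpha:
        fit = fit_linear(series)
        fit.score_test_p = p
        return fit

    def rss_at(psi: float) -> float:
        design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r)

    rss = np.array([rss_at(psi) for psi in grid])
    best = int(np.argmin(rss))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = None
        try:
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-4})
        except Exception:  # pragma: no cover - fallback to grid optimum
            pass
        psi = float(res.x) if res is not None and rss_at(float(res.x)) <= rss[best] else float(grid[best])
    else:
        psi = float(grid[best])

    design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    beta, _, _, ci = _ols_ci(x, y, design)
    return TrendFit(
        kind="segmented",
        slopes=(float(beta[1]), float(beta[1] + beta[2])),
        intercept=float(beta[0]),
        breakpoint_year=psi,
        score_test_p=p,
        ci=ci,
    )


# --------------------------------------------------------------------------
# Robust anomaly detection
# --------------------------------------------------------------------------


@dataclass
class AnomalyResult:
    """Robust standardized residual for one designated year.

    flagged is one-sided: only residuals above ``threshold`` flag, since the
    surveillance question is whether rates were unusually *high*.
    """

    year: int
    robust_z: float
    flagged: bool


def robust_anomaly(
    series: RateSeries,
    target_years: tuple[int, ...] = (2020, 2021),
    threshold: float = 2.0,
    calibrated: bool = True,
) -> list[AnomalyResult]:
    """Robust standardized residuals for designated years.

    A Theil–Sen line (median of pairwise slopes, median-based intercept) is
    fitted to all non-target years; each target year's residual from that
    line is standardized by a robust scale built on 1.4826 x MAD of the
    reference residuals.  Excluding the targets from the fit prevents an
    anomalous year from masking itself.  Flagging is one-sided
    (robust_z > threshold).  The statistic is invariant to adding a constant
    to the series and to positive rescaling.

    With ``calibrated`` (the default) the denominator carries three standard
    finite-sample corrections so that the null exceedance probability of
    the z > 2 flag stays near its nominal level on short series:

    * the out-of-sample prediction factor sqrt(1 + 1/n + (x0 - xbar)^2/Sxx)
      (a target year is extrapolated, not interpolated, from the reference
      span, and its prediction error grows with the leverage);
    * the residual degrees-of-freedom factor sqrt(n / (n - 2)) for the
      two-parameter trend fit;
    * the Croux–Rousseeuw small-sample MAD consistency factor n / (n - 0.8).

    ``calibrated=False`` gives the plain ``residual / (1.4826 x MAD)``
    statistic.
    """
    years = series.years
    rates = series.rates
    ref_mask = ~np.isin(years, target_years)
    n_ref = int(ref_mask.sum())
    if n_ref < 5:
        raise InsufficientDataError(
            f"robust anomaly detection requires >= 5 reference years, got {n_ref}"
        )
    xr, yr = years[ref_mask].astype(float), rates[ref_mask]
    ts = stats.theilslopes(yr, xr)
    resid_ref = yr - (ts.intercept + ts.slope * xr)
    scale = stats.median_abs_deviation(resid_ref, scale="normal")  # 1.4826 * MAD
    if calibrated:
        scale *= np.sqrt(n_ref / (n_ref - 2)) * n_ref / (n_ref - 0.8)
    xbar = xr.mean()
    sxx = float(np.sum((xr - xbar) ** 2))

    out: list[AnomalyResult] = []
    for year in target_years:
        if year not in years:
            continue
        obs = series.value_at(year)
        resid = obs - (ts.intercept + ts.slope * year)
        denom = scale
        if calibrated:
            denom = scale * np.sqrt(1.0 + 1.0 / n_ref + (year - xbar) ** 2 / sxx)
        if denom == 0.0:
            z = float(np.inf) if resid > 0 else (float(-np.inf) if resid < 0 else 0.0)
        else:
            z = float(resid / denom)
        out.append(AnomalyResult(year=int(year), robust_z=z, flagged=bool(z > threshold)))
    return out
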