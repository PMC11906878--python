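"""Per-country trend fitting and lockdown-anomaly classification.

Yearly record counts in a fixed calendar window (2010-2023 in the study
design) are smoothed with a cubic smoothing spline; the fitted value for the
focal year (2020) comes with a 95% pointwise Bayesian interval, and the
observed count is classified ``below`` / ``within`` / ``above`` that
interval.  Falling outside the interval is the "significant at 0.05"
statement of the anomaly test.

Spline form
-----------
The fit minimises the penalised least-squares criterion

    sum_i (y_i - f(x_i))^2 + lambda * integral f''(t)^2 dt

over natural cubic splines, in the Green-Silverman matrix form: with
``K = Q R^-1 Q^T`` the penalty matrix on knot values, the fitted values are
``f = (I + lambda K)^-1 y`` and the smoother matrix is
``S = (I + lambda K)^-1``.  Years are rescaled to [0, 1] before the penalty
is formed.

The user-facing smoothing parameter follows the classical ``spar``
convention: ``lambda = r * 256**(3*spar - 1)`` with ``r`` the ratio of the
traces of the data-fidelity matrix (the identity, trace ``n``) and the
penalty matrix ``K``.  ``spar`` in (0, 1]; lower values allow a wigglier
curve.  The study design evaluates spar = 0.4, 0.5 and 0.6.

The 95% interval is the Wahba-type Bayesian pointwise interval:
``f_i +/- z_{0.975} * sigma * sqrt(S_ii)`` with ``sigma^2`` estimated as the
residual sum of squares over the residual degrees of freedom ``n - tr(S)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import linalg
from scipy.interpolate import CubicSpline
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TrendFit",
    "SmoothingSplineTrend",
    "InsufficientDataError",
    "fit_smoothing_spline",
    "classify_anomaly",
    "DEFAULT_SMOOTHING_PARAMS",
]

#: The three smoothing parameters of the study's sensitivity design.
DEFAULT_SMOOTHING_PARAMS: tuple[float, ...] = (0.4, 0.5, 0.6)

AnomalyClass = Literal["below", "within", "above"]


class InsufficientDataError(ValueError):
    """Fewer than four distinct years — too few knots for a cubic spline."""


def _natural_spline_penalty(t: np.ndarray) -> np.ndarray:
    """Penalty matrix K = Q R^-1 Q^T for natural cubic splines at knots t."""
    n = t.size
    h = np.diff(t)
    # Q: n x (n-2); column j couples knots j-1, j, j+1  (0-based interior j)
    Q = np.zeros((n, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
    # R: (n-2) x (n-2) symmetric tridiagonal
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
    return Q @ linalg.solve(R, Q.T, assume_a="pos")


def lambda_from_spar(spar: float, penalty: np.ndarray, n: int) -> float:
    """Map spar in (0, 1] to the roughness-penalty weight lambda.

    ``lambda = r * 256**(3*spar - 1)`` with ``r = tr(I_n) / tr(K)``; the
    mapping is strictly increasing in spar, so larger spar means a stiffer
    (closer to linear) fit.
    """
    if not 0.0 < spar <= 1.0:
        raise ValueError(f"smoothing parameter must lie in (0, 1], got {spar}")
    r = n / np.trace(penalty)
    return float(r * 256.0 ** (3.0 * spar - 1.0))


@dataclass
class TrendFit:
    """A fitted per-country yearly trend with its focal-year interval."""

    country_code: str | None
    smoothing_param: float
    years: np.ndarray
    observed: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    focal_year: int
    lambda_: float
    edf: float
    sigma2: float

    @property
    def _focal_index(self) -> int:
        idx = np.flatnonzero(self.years == self.focal_year)
        if idx.size == 0:
            raise ValueError(f"focal year {self.focal_year} not in fit years")
        return int(idx[0])

    @property
    def focal_fitted(self) -> float:
        return float(self.fitted[self._focal_index])

    @property
    def focal_interval(self) -> tuple[float, float]:
        i = self._focal_index
        return float(self.ci_low[i]), float(self.ci_high[i])

    @property
    def anomaly_class(self) -> AnomalyClass:
        cls, _ = classify_anomaly(self, float(self.observed[self._focal_index]))
        return cls


class SmoothingSplineTrend(BaseEstimator, RegressorMixin):
    """Cubic smoothing-spline trend with Bayesian pointwise intervals.

    Parameters
    ----------
    smoothing_param : float, default 0.5
        spar-style smoothing parameter in (0, 1]; mapped to the penalty
        weight as ``lambda = (n / tr(K)) * 256**(3*spar - 1)``.
    ci_level : float, default 0.95
        Pointwise interval level.
    log_scale : bool, default False
        Fit on ``log10(y + 1)`` and back-transform fitted values and
        interval limits.  The default (raw counts) matches the study design.
    exclude_focal : bool, default False
        Leave the focal year out of the fit and predict it from the
        remaining years (interval width at the focal year is then
        interpolated between the bracketing knots — an approximation).
    focal_year : int, default 2020
        Year whose observation is classified against the interval.

    Attributes
    ----------
    years_, observed_ : ndarray — training data, sorted by year.
    fitted_, se_, ci_low_, ci_high_ : ndarray — per-year fit and interval.
    lambda_ : float — realised penalty weight.
    edf_ : float — equivalent degrees of freedom, tr(S).
    sigma2_ : float — residual variance estimate RSS / (n - tr(S)).
    """

    def __init__(self, smoothing_param: float = 0.5, ci_level: float = 0.95,
                 log_scale: bool = False, exclude_focal: bool = False,
                 focal_year: int = 2020):
        self.smoothing_param = smoothing_param
        self.ci_level = ci_level
        self.log_scale = log_scale
        self.exclude_focal = exclude_focal
        self.focal_year = focal_year

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Fit the spline to years ``X`` (1-d or (n, 1)) and counts ``y``."""
        years = np.asarray(X, dtype=float).reshape(-1)
        counts = np.asarray(y, dtype=float).reshape(-1)
        if years.size != counts.size:
            raise ValueError("years and counts differ in length")
        if np.unique(years).size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct years, got {np.unique(years).size}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        order = np.argsort(years)
        years, counts = years[order], counts[order]
        self.years_ = years.astype(int)
        self.observed_ = counts.copy()

        fit_mask = np.ones(years.size, dtype=bool)
        if self.exclude_focal:
            fit_mask = years != self.focal_year
        t_all = (years - years[0]) / max(years[-1] - years[0], 1.0)
        t = t_all[fit_mask]
        z = counts[fit_mask]
        if self.log_scale:
            z = np.log10(z + 1.0)
        n = t.size
        if np.unique(t).size < 4:
            raise InsufficientDataError("need >= 4 distinct fitting years")

        K = _natural_spline_penalty(t)
        lam = lambda_from_spar(self.smoothing_param, K, n)
        S = linalg.inv(np.eye(n) + lam * K)
        f = S @ z
        edf = float(np.trace(S))
        rss = float(np.sum((z - f) ** 2))
        res_df = max(n - edf, 1e-8)
        sigma2 = rss / res_df
        zq = norm.ppf(0.5 + self.ci_level / 2.0)
        se = np.sqrt(np.clip(sigma2 * np.diag(S), 0.0, None))

        # evaluate the curve (and an interpolated se) at every supplied year
        if self.exclude_focal:
            curve = CubicSpline(t, f, bc_type="natural")
            f_all = curve(t_all)
            se_all = np.interp(t_all, t, se)
        else:
            f_all, se_all = f, se

        if self.log_scale:
            lo = 10.0 ** (f_all - zq * se_all) - 1.0
            hi = 10.0 ** (f_all + zq * se_all) - 1.0
            f_out = 10.0 ** f_all - 1.0
            se_out = se_all  # on the log scale
        else:
            lo, hi = f_all - zq * se_all, f_all + zq * se_all
            f_out, se_out = f_all, se_all

        self.fitted_ = np.asarray(f_out, dtype=float)
        self.se_ = np.asarray(se_out, dtype=float)
        self.ci_low_ = np.asarray(lo, dtype=float)
        self.ci_high_ = np.asarray(hi, dtype=float)
        self.lambda_ = lam
        self.edf_ = edf
        self.sigma2_ = sigma2
        self._curve_knots_ = (t, f)
        self._t_scale_ = (years[0], max(years[-1] - years[0], 1.0))
        return self

    # ------------------------------------------------------------------
    def predict(self, X):
        """Evaluate the fitted curve at arbitrary years (natural spline)."""
        years = np.asarray(X, dtype=float).reshape(-1)
        t0, span = self._t_scale_
        t = (years - t0) / span
        kt, kf = self._curve_knots_
        curve = CubicSpline(kt, kf, bc_type="natural")
        out = curve(t)
        if self.log_scale:
            out = 10.0 ** out - 1.0
        return out

    # ------------------------------------------------------------------
    def to_trend_fit(self, country_code: str | None = None) -> TrendFit:
        """Package the fitted state as a :class:`TrendFit` record."""
        return TrendFit(
            country_code=country_code,
            smoothing_param=self.smoothing_param,
            years=self.years_,
            observed=self.observed_,
            fitted=self.fitted_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            focal_year=self.focal_year,
            lambda_=self.lambda_,
            edf=self.edf_,
            sigma2=self.sigma2_,
        )


def fit_smoothing_spline(
    years: Sequence[int],
    counts: Sequence[float],
    smoothing_param: float = 0.5,
    focal_year: int = 2020,
    country_code: str | None = None,
    log_scale: bool = False,
    exclude_focal: bool = False,
) -> TrendFit:
    """Fit the yearly trend spline and return a :class:`TrendFit`.

    Thin wrapper over :class:`SmoothingSplineTrend`.
    """
    est = SmoothingSplineTrend(
        smoothing_param=smoothing_param, log_scale=log_scale,
        exclude_focal=exclude_focal, focal_year=focal_year)
    est.fit(np.asarray(years), np.asarray(counts))
    return est.to_trend_fit(country_code)


def classify_anomaly(trend_fit: TrendFit,
                     observed_focal: float) -> tuple[AnomalyClass, bool]:
    """Classify the focal-year observation against the fitted interval.

    Returns ``(anomaly_class, significant)`` where ``significant`` is True
    exactly when the observation falls outside the 95% interval (the
    "p < 0.05" statement of the anomaly test).
    """
    lo, hi = trend_fit.focal_interval
    if observed_focal < lo:
        return "below", True
    if observed_focal > hi:
        return "above", True
    return "within", False
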