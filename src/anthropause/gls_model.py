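"""Heteroscedastic generalised least squares for the change-in-records model.

The response ``log10(change_pct + 100)`` is regressed on the stringency
index, the change in park visitors, log10 population size and the economic
class (reference level "developed"), optionally with a stringency x class
interaction.  Residual diagnostics of the ordinary fit show unequal spread
across economic classes, so the linear model is extended by GLS with a
distinct residual variance per class: a "varIdent"-style structure

    Var(eps_i) = sigma^2 * delta_{g(i)}^2,   delta_reference = 1.

Estimation maximises the Gaussian likelihood jointly over coefficients and
variance multipliers by blockwise profile ascent: given multipliers, the
coefficient step is a weighted least squares; given coefficients, the
multiplier step is the closed-form per-group residual variance.  Each step
maximises the same objective, so the log-likelihood is non-decreasing across
iterations; convergence is declared when successive log-likelihoods differ
by less than 1e-8 (at most 200 iterations).  REML estimation profiles
coefficients and scale analytically and optimises the multipliers
numerically on the log scale.

Model comparison (likelihood-ratio test, per-term ANOVA) uses ML
log-likelihoods, reported on the conventional scale that includes the
-n/2 log(2*pi) constant.  Coefficient p-values use the t distribution with
n - p degrees of freedom, the usual small-sample GLS convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._countries import ECONOMIC_CLASSES

__all__ = [
    "GLSModelSpec",
    "GLSFit",
    "HeteroscedasticGLS",
    "ConvergenceError",
    "RankDeficiencyError",
    "NestingViolationError",
    "build_design",
    "fit_gls",
    "likelihood_ratio_test",
    "anova_terms",
    "conditional_effects",
    "residual_variance_test",
]

LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Profile ascent failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class RankDeficiencyError(ValueError):
    """Singular design matrix; names the aliased columns."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design matrix is rank deficient; "
                         f"aliased column(s): {aliased}")


class NestingViolationError(ValueError):
    """The 'alternative' model has a lower likelihood than the null."""


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------
class HeteroscedasticGLS(BaseEstimator, RegressorMixin):
    """Linear model with one residual-variance multiplier per group.

    Parameters
    ----------
    estimation : {"ml", "reml"}, default "ml"
        Maximum likelihood (required for model comparison) or restricted
        maximum likelihood (less biased variance components).
    tol : float, default 1e-8
        Convergence tolerance on successive log-likelihoods.
    max_iter : int, default 200
        Iteration cap for the ML profile ascent.
    fix_unit_multipliers : bool, default False
        Force every multiplier to 1; the fit then reduces to OLS exactly.

    Attributes
    ----------
    coef_ : ndarray of shape (p,) — coefficients (design supplied as-is;
        include an intercept column if one is wanted).
    group_levels_ : ndarray — variance-group levels, reference first.
    variance_multipliers_ : ndarray — one multiplier per level; the
        reference multiplier is identically 1.
    sigma2_ : float — residual variance of the reference group.
    loglik_ : float — maximised log-likelihood (ML or REML scale).
    cov_params_ : ndarray (p, p) — coefficient covariance.
    df_resid_ : int — n - p.
    n_iter_ : int — profile-ascent iterations used.
    loglik_trace_ : list of float — per-iteration log-likelihoods (ML).
    """

    def __init__(self, estimation: Literal["ml", "reml"] = "ml",
                 tol: float = 1e-8, max_iter: int = 200,
                 fix_unit_multipliers: bool = False):
        self.estimation = estimation
        self.tol = tol
        self.max_iter = max_iter
        self.fix_unit_multipliers = fix_unit_multipliers

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
        from scipy.linalg import qr as _qr

        n, p = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # pivoted QR: the trailing pivots index the aliased columns
            _, _, piv = _qr(X, mode="economic", pivoting=True)
            bad = piv[rank:]
            raise RankDeficiencyError([str(names[j]) for j in sorted(bad)])

    def _loglik_ml(self, r: np.ndarray, delta_i: np.ndarray,
                   sigma2: float) -> float:
        n = r.size
        return float(-0.5 * n * LOG2PI
                     - 0.5 * np.sum(np.log(sigma2 * delta_i ** 2))
                     - 0.5 * np.sum(r ** 2 / (sigma2 * delta_i ** 2)))

    # -- fitting -------------------------------------------------------
    def fit(self, X, y, groups=None):
        """Fit to design ``X`` (n, p), response ``y`` and group labels.

        ``groups`` may be None (single group; plain OLS by ML).  Each group
        must hold at least 2 observations.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        n, p = X.shape
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{j}" for j in range(p)]
        self._check_rank(X, names)
        if groups is None:
            groups = np.zeros(n, dtype=int)
        groups = np.asarray(groups)
        levels, gidx = np.unique(groups, return_inverse=True)
        # keep the declared economic-class order when it applies
        if set(map(str, levels)) <= set(ECONOMIC_CLASSES):
            order = [lv for lv in ECONOMIC_CLASSES if lv in set(map(str, levels))]
            remap = {lv: k for k, lv in enumerate(order)}
            gidx = np.array([remap[str(g)] for g in groups])
            levels = np.array(order, dtype=object)
        counts = np.bincount(gidx, minlength=levels.size)
        if (counts < 2).any():
            small = [str(levels[k]) for k in np.flatnonzero(counts < 2)]
            raise ValueError(f"variance group(s) with < 2 observations: "
                             f"{small}")
        G = levels.size

        if self.fix_unit_multipliers or G == 1:
            delta = np.ones(G)
            beta, r = self._wls(X, y, np.ones(n))
            sigma2 = float(np.mean(r ** 2))
            if self.estimation == "reml":
                sigma2 = float(np.sum(r ** 2) / (n - p))
            trace = [self._loglik_ml(r, np.ones(n), max(sigma2, 1e-300))]
            n_iter = 1
        elif self.estimation == "ml":
            delta, beta, r, sigma2, trace, n_iter = self._fit_ml(
                X, y, gidx, G, counts)
        else:
            delta, beta, r, sigma2, trace, n_iter = self._fit_reml(
                X, y, gidx, G, counts, p)

        delta_i = delta[gidx]
        w = 1.0 / delta_i ** 2
        XtWX = X.T @ (X * w[:, None])
        self.coef_ = beta
        self.group_levels_ = levels
        self.variance_multipliers_ = delta
        self.sigma2_ = sigma2
        # Wald inference uses the (n - p)-denominator scale even under ML,
        # the usual small-sample GLS convention
        sigma2_inf = sigma2 * n / (n - p) if self.estimation == "ml" else sigma2
        self.cov_params_ = sigma2_inf * np.linalg.inv(XtWX)
        self.df_resid_ = n - p
        self.n_iter_ = n_iter
        self.loglik_trace_ = trace
        if self.estimation == "ml":
            self.loglik_ = trace[-1]
        else:
            self.loglik_ = self._reml_loglik(X, y, delta, gidx, p)
        self.fitted_ = X @ beta
        self.residuals_ = y - self.fitted_
        self.normalized_residuals_ = self.residuals_ / (
            np.sqrt(sigma2) * delta_i)
        self._gidx_ = gidx
        return self

    @staticmethod
    def _wls(X, y, w):
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return beta, y - X @ beta

    def _fit_ml(self, X, y, gidx, G, counts):
        n = y.size
        delta = np.ones(G)
        trace: list[float] = []
        for it in range(1, self.max_iter + 1):
            w = 1.0 / delta[gidx] ** 2
            beta, r = self._wls(X, y, w)
            # closed-form multiplier step: per-group residual variance
            v = np.bincount(gidx, weights=r ** 2, minlength=G) / counts
            v = np.clip(v, 1e-300, None)
            sigma2 = v[0]
            delta = np.sqrt(v / sigma2)
            ll = self._loglik_ml(r, delta[gidx], sigma2)
            trace.append(ll)
            if it > 1 and abs(trace[-1] - trace[-2]) < self.tol:
                return delta, beta, r, float(sigma2), trace, it
        raise ConvergenceError(
            f"ML profile ascent did not converge in {self.max_iter} "
            f"iterations (last delta log-lik "
            f"{abs(trace[-1] - trace[-2]):.3e})", trace)

    def _reml_loglik(self, X, y, delta, gidx, p):
        n = y.size
        w = 1.0 / delta[gidx] ** 2
        beta, r = self._wls(X, y, w)
        rss_w = float(np.sum(w * r ** 2))
        sigma2 = rss_w / (n - p)
        XtWX = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(XtWX)
        return float(-0.5 * (n - p) * (LOG2PI + np.log(sigma2) + 1.0)
                     - np.sum(np.log(delta[gidx]))
                     - 0.5 * logdet)

    def _fit_reml(self, X, y, gidx, G, counts, p):
        n = y.size

        def negloglik(log_delta_rest):
            delta = np.concatenate([[1.0], np.exp(log_delta_rest)])
            return -self._reml_loglik(X, y, delta, gidx, p)

        # warm start at the ML solution
        d_ml, *_ = self._fit_ml(X, y, gidx, G, counts)
        x0 = np.log(d_ml[1:])
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        delta = np.concatenate([[1.0], np.exp(res.x)])
        w = 1.0 / delta[gidx] ** 2
        beta, r = self._wls(X, y, w)
        rss_w = float(np.sum(w * r ** 2))
        sigma2 = rss_w / (n - p)
        return delta, beta, r, sigma2, [-res.fun], int(res.nit)

    # -- prediction ----------------------------------------------------
    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


# ----------------------------------------------------------------------
# model specification and design construction
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GLSModelSpec:
    """Specification of the change-in-records regression."""

    response: str = "log_change"
    interaction: bool = False
    estimation: Literal["ml", "reml"] = "ml"
    variance_groups: str = "economic_class"


CONTINUOUS_TERMS = ("stringency_index", "change_park_visitors",
                    "log10_population_size")


def build_design(frame: pd.DataFrame, interaction: bool = False,
                 response: str = "log_change"):
    """Expand the model frame into (X, y, groups, terms).

    Categorical terms use reference coding with "developed" as reference.
    ``terms`` maps each model term to its design-column names (the unit of
    the per-term ANOVA).
    """
    y = frame[response].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(frame))}
    terms: dict[str, list[str]] = {}
    for c in CONTINUOUS_TERMS:
        cols[c] = frame[c].to_numpy(dtype=float)
        terms[c] = [c]
    econ = frame["economic_class"].astype(str).to_numpy()
    dummy_names = []
    for lv in ECONOMIC_CLASSES[1:]:
        name = f"economic_class[{lv}]"
        cols[name] = (econ == lv).astype(float)
        dummy_names.append(name)
    terms["economic_class"] = dummy_names
    if interaction:
        inter_names = []
        for lv in ECONOMIC_CLASSES[1:]:
            name = f"stringency_index:economic_class[{lv}]"
            cols[name] = cols["stringency_index"] * cols[f"economic_class[{lv}]"]
            inter_names.append(name)
        terms["stringency_index:economic_class"] = inter_names
    X = pd.DataFrame(cols, index=frame.index)
    return X, y, econ, terms


@dataclass
class GLSFit:
    """A fitted heteroscedastic regression, ready for reporting."""

    spec: GLSModelSpec
    params: pd.DataFrame           # index: column; coef, se, t, p
    variance_multipliers: dict[str, float]
    loglik: float
    sigma2: float
    fitted: np.ndarray
    normalized_residuals: np.ndarray
    cov_params: pd.DataFrame
    terms: dict[str, list[str]]
    df_resid: int
    n_obs: int
    frame: pd.DataFrame = field(repr=False)
    estimator: HeteroscedasticGLS = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (coefficients, multipliers, loglik)."""
        return {
            "estimation": self.spec.estimation,
            "interaction": self.spec.interaction,
            "n_obs": self.n_obs,
            "log_likelihood": self.loglik,
            "sigma2": self.sigma2,
            "coefficients": {
                name: {"estimate": float(row["coef"]),
                       "se": float(row["se"]),
                       "t": float(row["t"]),
                       "p": float(row["p"])}
                for name, row in self.params.iterrows()},
            "variance_multipliers": {k: float(v) for k, v in
                                     self.variance_multipliers.items()},
        }


def fit_gls(spec: GLSModelSpec, frame: pd.DataFrame,
            fix_unit_multipliers: bool = False) -> GLSFit:
    """Fit the change-in-records model on an assembled frame."""
    X, y, groups, terms = build_design(frame, interaction=spec.interaction,
                                       response=spec.response)
    dead = [c for c in X.columns
            if c != "intercept" and not np.any(X[c].to_numpy())]
    if dead:
        warnings.warn(f"dropping all-zero design column(s) {dead} "
                      "(rank deficiency)")
        X = X.drop(columns=dead)
        terms = {t: [c for c in cols if c not in dead]
                 for t, cols in terms.items()}
    est = HeteroscedasticGLS(estimation=spec.estimation,
                             fix_unit_multipliers=fix_unit_multipliers)
    est.feature_names_in_ = list(X.columns)
    est.fit(X.to_numpy(), y, groups=groups)
    se = np.sqrt(np.diag(est.cov_params_))
    tval = est.coef_ / se
    pval = 2.0 * stats.t.sf(np.abs(tval), est.df_resid_)
    params = pd.DataFrame({"coef": est.coef_, "se": se, "t": tval,
                           "p": pval}, index=X.columns)
    mult = {str(lv): float(d) for lv, d in
            zip(est.group_levels_, est.variance_multipliers_)}
    return GLSFit(
        spec=spec, params=params, variance_multipliers=mult,
        loglik=float(est.loglik_), sigma2=float(est.sigma2_),
        fitted=est.fitted_, normalized_residuals=est.normalized_residuals_,
        cov_params=pd.DataFrame(est.cov_params_, index=X.columns,
                                columns=X.columns),
        terms=terms, df_resid=est.df_resid_, n_obs=len(frame),
        frame=frame, estimator=est)


# ----------------------------------------------------------------------
# inference
# ----------------------------------------------------------------------
def likelihood_ratio_test(loglik_null: float, loglik_alt: float,
                          df: int, tol: float = 1e-6
                          ) -> tuple[float, float]:
    """Chi-square likelihood-ratio test for nested ML fits.

    ``statistic = 2 (loglik_alt - loglik_null)``; the p-value is the
    chi-square upper tail with ``df`` degrees of freedom.  Both
    log-likelihoods must come from ML fits of nested models.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if loglik_alt < loglik_null - tol:
        raise NestingViolationError(
            f"alternative log-likelihood {loglik_alt} is below the null "
            f"{loglik_null}; models are not nested or fits did not converge")
    statistic = max(0.0, 2.0 * (loglik_alt - loglik_null))
    p = float(stats.chi2.sf(statistic, df))
    return statistic, p


def anova_terms(fit: GLSFit) -> pd.DataFrame:
    """Marginal (Wald) F test for every model term; interaction last.

    Each term's coefficients are tested jointly against zero using the
    coefficient covariance:  F = b' V^-1 b / q  on (q, n - p) degrees of
    freedom.  Terms whose design columns are all zero are excluded with a
    rank-deficiency notice.
    """
    rows = []
    order = [t for t in fit.terms if ":" not in t] + \
            [t for t in fit.terms if ":" in t]
    for term in order:
        cols = fit.terms[term]
        live = [c for c in cols
                if c in fit.params.index and fit.params.loc[c, "se"] > 0]
        if not live:
            warnings.warn(f"term {term!r} has no estimable columns "
                          "(all zero); excluded from the ANOVA")
            continue
        b = fit.params.loc[live, "coef"].to_numpy()
        V = fit.cov_params.loc[live, live].to_numpy()
        q = len(live)
        F = float(b @ np.linalg.solve(V, b) / q)
        p = float(stats.f.sf(F, q, fit.df_resid))
        rows.append((term, q, fit.df_resid, F, p))
    return pd.DataFrame(rows, columns=["term", "df_num", "df_den",
                                       "F", "p"])


def conditional_effects(fit: GLSFit, focal_term: str,
                        n_grid: int = 50, level: float = 0.95
                        ) -> pd.DataFrame:
    """Conditional-effect profile of one predictor.

    Continuous covariates other than the focal one are held at their sample
    means; the categorical term is averaged with weights proportional to the
    observed class frequencies.  The band comes from the coefficient
    covariance (t quantile, n - p df).

    Returns a frame with columns ``value``, ``predicted``, ``lo``, ``hi``;
    for the categorical focal term ``value`` holds the class labels.
    """
    known = set(CONTINUOUS_TERMS) | {"economic_class"}
    if focal_term not in known or focal_term not in fit.terms:
        raise ValueError(f"focal term {focal_term!r} not in the model")
    frame = fit.frame
    colnames = list(fit.params.index)
    base: dict[str, float] = {"intercept": 1.0}
    for c in CONTINUOUS_TERMS:
        base[c] = float(frame[c].mean())
    econ = frame["economic_class"].astype(str)
    freqs = {lv: float((econ == lv).mean()) for lv in ECONOMIC_CLASSES}
    for lv in ECONOMIC_CLASSES[1:]:
        base[f"economic_class[{lv}]"] = freqs[lv]

    if focal_term == "economic_class":
        grid_labels = list(ECONOMIC_CLASSES)
        rows = []
        for lv in grid_labels:
            row = dict(base)
            for other in ECONOMIC_CLASSES[1:]:
                row[f"economic_class[{other}]"] = float(other == lv)
            rows.append(row)
        values = grid_labels
    else:
        lo_v, hi_v = float(frame[focal_term].min()), float(frame[focal_term].max())
        grid = np.linspace(lo_v, hi_v, n_grid)
        rows = []
        for v in grid:
            row = dict(base)
            row[focal_term] = float(v)
            rows.append(row)
        values = grid

    # resolve interaction columns from their parents
    design = []
    for row in rows:
        vec = []
        for name in colnames:
            if name in row:
                vec.append(row[name])
            elif ":" in name:
                a, b = name.split(":", 1)
                vec.append(row[a] * row[b])
            else:  # pragma: no cover - defensive
                raise KeyError(name)
        design.append(vec)
    Xg = np.asarray(design, dtype=float)
    beta = fit.params["coef"].to_numpy()
    V = fit.cov_params.to_numpy()
    pred = Xg @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, V, Xg))
    q = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
    return pd.DataFrame({"value": values, "predicted": pred,
                         "lo": pred - q * se, "hi": pred + q * se})


def residual_variance_test(residuals: Sequence[float],
                           groups: Sequence,
                           center: Literal["median", "mean"] = "median"
                           ) -> tuple[float, float]:
    """Levene test for homogeneity of residual variance across groups.

    The default centring is the median (the Brown-Forsythe variant, robust
    to non-normal residuals); ``center="mean"`` gives the classical Levene
    test.  Groups with fewer than 2 observations are excluded with a
    warning.
    """
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups)
    samples = []
    for lv in pd.unique(groups):
        vals = residuals[groups == lv]
        if vals.size < 2:
            warnings.warn(f"group {lv!r} has < 2 observations; excluded "
                          "from the variance test")
            continue
        samples.append(vals)
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    stat, p = stats.levene(*samples, center=center)
    return float(stat), float(p)
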