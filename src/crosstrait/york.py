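"""Fixed-intercept York regression with heterogeneity and outlier tests.

This is the core cross-trait comparison engine: an errors-in-variables
regression of trait-Y log odds ratios on trait-X log odds ratios with the
intercept pinned at zero, weighting each variant by the variance of its
residual given estimation error in *both* GWAS and any estimator
correlation from sample overlap.

The slope estimate minimizes

    S(b) = sum_i (beta_y_i - b * beta_x_i)^2 / v_i(b),
    v_i(b) = se_y_i^2 + b^2 se_x_i^2 - 2 b r_i se_x_i se_y_i,

where v_i(b) is the variance of the residual of a point assumed to lie on
the line through the origin with slope b. At the null of a single shared
linear relationship, S is asymptotically chi-square with n - 1 degrees of
freedom (one free parameter), which yields an analytic global
heterogeneity test. A variant is an outlier when letting it follow its own
separate distribution (one extra parameter) improves the fit more than a
chi-square(1) allows: its residual against the leave-one-out slope is
tested, Bonferroni-corrected across variants.

Everything here is deterministic: the iteration starts from the
weighted-least-squares-through-origin slope, so no seeds are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pairs import PairsLike, as_pairs_frame

__all__ = [
    "YorkRegression",
    "YorkRegressionResults",
    "OutlierReport",
    "york_fit_fixed_intercept",
    "global_heterogeneity_test",
    "outlier_scan",
]


def _residual_variance(b, se_x, se_y, r):
    return se_y**2 + b**2 * se_x**2 - 2.0 * b * r * se_x * se_y


def _objective(b, x, y, se_x, se_y, r):
    v = _residual_variance(b, se_x, se_y, r)
    return float(np.sum((y - b * x) ** 2 / v))


def _objective_grad(b, x, y, se_x, se_y, r):
    v = _residual_variance(b, se_x, se_y, r)
    dv = 2.0 * b * se_x**2 - 2.0 * r * se_x * se_y
    e = y - b * x
    return float(np.sum(-2.0 * x * e / v - e**2 * dv / v**2))


class YorkRegression:
    """Errors-in-variables regression through the origin of Y on X effects.

    Parameters
    ----------
    pairs : DataFrame or sequence of EffectPair
        Bivariate effect estimates with standard errors and optional
        estimator correlation (columns ``beta_x, se_x, beta_y, se_y,
        r_est``).

    Examples
    --------
    >>> import pandas as pd
    >>> pairs = pd.DataFrame({"beta_x": [1, 2, 3], "se_x": [0.1] * 3,
    ...                       "beta_y": [2, 4, 6], "se_y": [0.1] * 3})
    >>> res = YorkRegression(pairs).fit()
    >>> round(res.slope, 10)
    2.0
    """

    def __init__(self, pairs: PairsLike):
        df = as_pairs_frame(pairs)
        if len(df) < 2:
            raise ValueError(
                f"insufficient points: need >= 2, got {len(df)}")
        self.data = df
        self._x = df["beta_x"].to_numpy(float)
        self._y = df["beta_y"].to_numpy(float)
        self._sx = df["se_x"].to_numpy(float)
        self._sy = df["se_y"].to_numpy(float)
        self._r = df["r_est"].to_numpy(float)

    # -- internal fitting pieces -------------------------------------------

    def _check_variances(self, b):
        v = _residual_variance(b, self._sx, self._sy, self._r)
        if np.any(v <= 0):
            bad = self.data["variant_id"].to_numpy()[v <= 0]
            raise ValueError(
                "non-positive residual variance at slope "
                f"{b:.6g} for variant(s) {bad.tolist()} "
                "(|r_est| too close to 1)")
        return v

    def _wls_slope(self):
        # error only in y: the natural deterministic starting point
        w = 1.0 / self._sy**2
        return float(np.sum(w * self._x * self._y)
                     / np.sum(w * self._x**2))

    def _fixed_point(self, b0, tol, max_iter):
        """York's iterative reweighting, specialised to a zero intercept."""
        wx = 1.0 / self._sx**2
        wy = 1.0 / self._sy**2
        alpha = np.sqrt(wx * wy)
        b = b0
        for it in range(1, max_iter + 1):
            self._check_variances(b)
            W = wx * wy / (wx + b**2 * wy - 2.0 * b * self._r * alpha)
            beta = W * (self._x / wy + b * self._y / wx
                        - (b * self._x + self._y) * self._r / alpha)
            denom = np.sum(W * beta * self._x)
            if denom == 0.0:
                return b, it, False
            b_new = float(np.sum(W * beta * self._y) / denom)
            if not np.isfinite(b_new):
                return b, it, False
            if abs(b_new - b) < tol:
                return b_new, it, True
            b = b_new
        return b, max_iter, False

    def _bracket_minimize(self, b0):
        args = (self._x, self._y, self._sx, self._sy, self._r)
        half_width = 10.0 * max(1.0, abs(b0))
        res = optimize.minimize_scalar(
            _objective, bounds=(b0 - half_width, b0 + half_width),
            args=args, method="bounded", options={"xatol": 1e-12})
        return float(res.x)

    def fit(self, tol: float = 1e-10, max_iter: int = 100
            ) -> "YorkRegressionResults":
        """Fit the slope and evaluate the goodness-of-fit statistic.

        The fixed-point iteration starts at the WLS-through-origin slope
        and stops when the slope moves by less than ``tol``; if it fails
        to converge (e.g. cycles), a bracketing 1-D minimization of S(b)
        takes over. The standard error comes from the curvature of S at
        the solution, ``se = sqrt(2 / S''(b))``.
        """
        args = (self._x, self._y, self._sx, self._sy, self._r)
        b0 = self._wls_slope()
        b, n_iter, converged = self._fixed_point(b0, tol, max_iter)
        if not converged or abs(_objective_grad(b, *args)) > 1e-6 * (
                1.0 + _objective(b, *args)):
            b = self._bracket_minimize(b if np.isfinite(b) else b0)
            converged = True
        v = self._check_variances(b)
        S = _objective(b, *args)

        h = 1e-5 * (1.0 + abs(b))
        d2 = (_objective_grad(b + h, *args)
              - _objective_grad(b - h, *args)) / (2.0 * h)
        se_slope = float(np.sqrt(2.0 / d2)) if d2 > 0 else np.nan

        n = len(self._x)
        df = n - 1
        p_global = float(stats.chi2.sf(S, df)) if df >= 1 else np.nan
        return YorkRegressionResults(
            model=self, slope=b, se_slope=se_slope, S=S, df=df,
            p_global=p_global, n_points=n, weights=1.0 / v,
            converged=converged, n_iter=n_iter)


@dataclass
class YorkRegressionResults:
    """Fitted fixed-intercept York regression.

    Attributes
    ----------
    slope : float
        Estimated trait-Y effect per unit trait-X effect.
    se_slope : float
        Standard error of the slope from the curvature of S.
    S : float
        Goodness-of-fit statistic at the solution.
    df : int
        Degrees of freedom of the global test, ``n_points - 1``.
    p_global : float
        Upper-tail chi-square probability of S: the global heterogeneity
        p-value. Small values mean no single line through the origin
        describes all variants.
    weights : numpy.ndarray
        Per-point weights ``1 / v_i`` at the solution.
    """

    model: YorkRegression
    slope: float
    se_slope: float
    S: float
    df: int
    p_global: float
    n_points: int
    weights: np.ndarray
    converged: bool
    n_iter: int
    intercept: float = 0.0

    def outlier_scan(self, alpha: float = 0.05) -> "OutlierReport":
        """Leave-one-out outlier scan; see :func:`outlier_scan`."""
        return outlier_scan(self.model.data, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Fixed-intercept York regression",
            "=" * 46,
            f"{'n variants':<28}{self.n_points:>18d}",
            f"{'slope (Y per X)':<28}{self.slope:>18.6f}",
            f"{'se(slope)':<28}{self.se_slope:>18.6f}",
            f"{'intercept (fixed)':<28}{self.intercept:>18.1f}",
            f"{'goodness of fit S':<28}{self.S:>18.4f}",
            f"{'df':<28}{self.df:>18d}",
            f"{'global heterogeneity P':<28}{self.p_global:>18.3g}",
            f"{'converged':<28}{str(self.converged):>18}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "se_slope": self.se_slope,
            "intercept": self.intercept, "S": self.S, "df": self.df,
            "p_global": self.p_global, "n_points": self.n_points,
            "converged": self.converged, "n_iter": self.n_iter,
        }


@dataclass
class OutlierReport:
    """Per-variant outlier statistics plus the refit without outliers."""

    table: pd.DataFrame
    refit: YorkRegressionResults | None
    alpha: float
    outliers: list = field(default_factory=list)


def york_fit_fixed_intercept(pairs: PairsLike, tol: float = 1e-10,
                             max_iter: int = 100) -> YorkRegressionResults:
    """Fit the through-origin York regression; convenience wrapper."""
    return YorkRegression(pairs).fit(tol=tol, max_iter=max_iter)


def global_heterogeneity_test(fit: YorkRegressionResults) -> float:
    """Upper-tail chi-square(df = n - 1) probability of the fit's S.

    Recomputes and stores ``p_global`` on the fit; raises if ``df < 1``.
    """
    if fit.df < 1:
        raise ValueError("global test needs df >= 1 (n_points >= 2)")
    fit.p_global = float(stats.chi2.sf(fit.S, fit.df))
    return fit.p_global


def outlier_scan(pairs: PairsLike, alpha: float = 0.05) -> OutlierReport:
    """Scan for variants that deviate from the shared linear relationship.

    For each variant j the model is refit on the remaining n - 1 points
    (an exact leave-one-out refit, slope ``b_-j``); the statistic

        stat_j = (beta_y_j - b_-j * beta_x_j)^2 / v_j(b_-j)

    is chi-square(1) under the null that variant j follows the common
    line. Raw p-values are Bonferroni-adjusted across the n tested
    variants; variants with adjusted p below ``alpha`` are flagged and the
    model refit without them.
    """
    df = as_pairs_frame(pairs)
    n = len(df)
    if n < 3:
        raise ValueError(
            "outlier scan needs >= 3 points (leave-one-out undefined "
            f"for testing); got {n}")
    rows = []
    for j in range(n):
        rest = df.drop(index=j).reset_index(drop=True)
        loo = YorkRegression(rest).fit()
        rj = df.loc[j]
        v_j = _residual_variance(loo.slope, rj.se_x, rj.se_y, rj.r_est)
        stat = (rj.beta_y - loo.slope * rj.beta_x) ** 2 / v_j
        p_raw = float(stats.chi2.sf(stat, 1))
        p_adj = min(1.0, n * p_raw)
        rows.append((rj.variant_id, float(stat), p_raw, p_adj,
                     p_adj < alpha, loo.slope))
    table = pd.DataFrame(
        rows, columns=["variant_id", "stat", "p_raw", "p_adj",
                       "is_outlier", "slope_loo"])
    outliers = table.loc[table["is_outlier"], "variant_id"].tolist()
    kept = df[~df["variant_id"].isin(outliers)]
    refit = YorkRegression(kept).fit() if len(kept) >= 2 else None
    return OutlierReport(table=table, refit=refit, alpha=alpha,
                         outliers=outliers)
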