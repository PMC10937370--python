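"""Line-model mixture classification of bivariate GWAS effects.

A *line model* is a zero-mean bivariate Gaussian prior on the true effect
sizes of a variant in two traits, concentrated around a line through the
origin. With slope s, scale sigma (prior SD of the trait-X effect) and
correlation rho (how tightly effects hug the line), the prior covariance is

    Sigma = [[sigma^2,        rho * s * sigma^2],
             [rho * s * sigma^2,  s^2 * sigma^2]].

Marginalizing the true effect over Gaussian estimation noise S (built from
the two standard errors and the estimator correlation), the observed pair
(beta_x, beta_y) is N(0, Sigma + S), which gives each variant a closed-form
marginal likelihood under each class, hence membership posteriors under
given prior class weights.

Class slopes are estimated by EM: the E-step computes membership
posteriors, the M-step maximizes each class's membership-weighted marginal
log-likelihood over its slope (scales, correlations and weights stay
fixed). One- vs two-class fits are compared by the log10 Bayes factor of
their maximized mixture marginal likelihoods.

In the gestational-diabetes application, class G (GDM-predominant, fitted
slope about 0.25) and class T (T2D-predominant, fitted slope about 1.53)
share scale 0.2 and correlation 0.99 with equal prior weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .pairs import EffectPair, PairsLike, as_pairs_frame

logger = logging.getLogger(__name__)

__all__ = [
    "LineModel",
    "LineModelMixture",
    "LineModelMixtureResults",
    "prior_covariance",
    "marginal_loglik",
    "class_posteriors",
    "fit_slopes_em",
    "log10_bayes_factor",
    "classify",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LineModel:
    """One class of bivariate effects concentrated around a line.

    Parameters
    ----------
    label : str
        Class name, e.g. ``"G"`` or ``"T"``.
    slope : float
        Trait-Y effect per unit trait-X effect (must be finite).
    scale : float
        Prior standard deviation of the trait-X effect (log-OR units);
        controls the magnitude of effects the class allows.
    cor : float
        Correlation concentrating effects around the line, in [-1, 1];
        values near 1 allow little deviation from the line.
    prior_weight : float
        Prior mixture weight in [0, 1].
    """

    label: str
    slope: float
    scale: float = 0.2
    cor: float = 0.99
    prior_weight: float = 0.5

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite (vertical lines are "
                             "not supported)")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive (got {self.scale})")
        if not -1.0 <= self.cor <= 1.0:
            raise ValueError(f"cor must be in [-1, 1] (got {self.cor})")
        if not 0.0 <= self.prior_weight <= 1.0:
            raise ValueError("prior_weight must be in [0, 1]")


def prior_covariance(model: LineModel) -> np.ndarray:
    """Prior covariance of the true (beta_x, beta_y) under a line model.

    Returns the 2x2 symmetric PSD matrix
    ``[[sigma^2, rho*s*sigma^2], [rho*s*sigma^2, s^2*sigma^2]]`` whose
    determinant is ``s^2 sigma^4 (1 - rho^2)``.
    """
    s, sig, rho = model.slope, model.scale, model.cor
    off = rho * s * sig**2
    return np.array([[sig**2, off], [off, s**2 * sig**2]])


def _check_weights(models) -> np.ndarray:
    w = np.array([m.prior_weight for m in models], float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"prior weights must sum to 1 (got {w.sum()})")
    return w


def _loglik_vector(bx, by, sx, sy, r, model: LineModel,
                   slope: float | None = None) -> np.ndarray:
    """Vectorized log marginal likelihood of observed pairs under a model.

    ``slope`` overrides the model slope (used by the EM M-step).
    """
    s = model.slope if slope is None else slope
    sig, rho = model.scale, model.cor
    c11 = sig**2 + sx**2
    c22 = s**2 * sig**2 + sy**2
    c12 = rho * s * sig**2 + r * sx * sy
    det = c11 * c22 - c12**2
    if np.any(det <= 0) or np.any(c11 <= 0):
        raise ValueError("total covariance (prior + sampling) is not "
                         "positive definite")
    with np.errstate(over="ignore"):
        quad = (c22 * bx**2 - 2.0 * c12 * bx * by + c11 * by**2) / det
        return -LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def _pair_arrays(pairs: PairsLike):
    df = as_pairs_frame(pairs)
    return df, (df["beta_x"].to_numpy(float), df["beta_y"].to_numpy(float),
                df["se_x"].to_numpy(float), df["se_y"].to_numpy(float),
                df["r_est"].to_numpy(float))


def marginal_loglik(pair: EffectPair, model: LineModel) -> float:
    """Log marginal likelihood of one observed pair under one line model.

    This is the log density of ``(beta_x, beta_y)`` under
    ``N(0, Sigma_model + S_pair)`` — the analytic marginalization of the
    true effect over the Gaussian estimation noise.
    """
    return float(_loglik_vector(
        np.array([pair.beta_x]), np.array([pair.beta_y]),
        np.array([pair.se_x]), np.array([pair.se_y]),
        np.array([pair.r_est]), model)[0])


def _posterior_matrix(arrays, models) -> np.ndarray:
    bx, by, sx, sy, r = arrays
    w = _check_weights(models)
    ll = np.column_stack([_loglik_vector(bx, by, sx, sy, r, m)
                          for m in models])
    logpost = np.log(w)[None, :] + ll
    underflow = ~np.isfinite(logpost).any(axis=1)
    norm = logsumexp(logpost, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        post = np.exp(logpost - norm)
    if underflow.any():
        warnings.warn("marginal likelihoods underflowed for "
                      f"{int(underflow.sum())} variant(s); returning "
                      "uniform posteriors for them")
        post[underflow] = 1.0 / len(models)
    return post


def class_posteriors(pair: EffectPair, models: list[LineModel]) -> dict:
    """Membership posterior of one pair across >= 2 line models.

    ``posterior_k`` is proportional to
    ``prior_weight_k * exp(marginal_loglik(pair, model_k))``, normalized in
    log space for stability; returns ``{label: probability}``.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    arrays = (np.array([pair.beta_x]), np.array([pair.beta_y]),
              np.array([pair.se_x]), np.array([pair.se_y]),
              np.array([pair.r_est]))
    post = _posterior_matrix(arrays, models)[0]
    return {m.label: float(p) for m, p in zip(models, post)}


class LineModelMixture:
    """Mixture of line models over a set of bivariate effect pairs.

    Scales, correlations and prior weights are treated as fixed
    hyperparameters; only slopes are free in :meth:`fit`.

    Parameters
    ----------
    pairs : DataFrame or sequence of EffectPair
    models : list of LineModel
        Initial class definitions; prior weights must sum to 1.
    """

    def __init__(self, pairs: PairsLike, models: list[LineModel]):
        self.data, self._arrays = _pair_arrays(pairs)
        if len(self.data) < len(models):
            raise ValueError("need at least as many pairs as classes")
        _check_weights(models)
        if len({m.label for m in models}) != len(models):
            raise ValueError("model labels must be unique")
        self.models = list(models)

    def loglikelihood(self, models: list[LineModel] | None = None) -> float:
        """Total log marginal likelihood of the data under the mixture."""
        models = self.models if models is None else models
        bx, by, sx, sy, r = self._arrays
        w = _check_weights(models)
        ll = np.column_stack([_loglik_vector(bx, by, sx, sy, r, m)
                              for m in models])
        return float(np.sum(logsumexp(np.log(w)[None, :] + ll, axis=1)))

    def _m_step_slope(self, model: LineModel, gamma: np.ndarray) -> float:
        bx, by, sx, sy, r = self._arrays

        def neg(s):
            return -float(np.sum(
                gamma * _loglik_vector(bx, by, sx, sy, r, model, slope=s)))

        res = optimize.minimize_scalar(neg, bounds=(-50.0, 50.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        return float(res.x)

    def fit(self, tol: float = 1e-8, max_iter: int = 1000
            ) -> "LineModelMixtureResults":
        """Estimate class slopes by EM.

        Iterates E (membership posteriors) and M (per-class 1-D
        maximization of the membership-weighted marginal log-likelihood
        over the slope) until the total log marginal likelihood improves
        by less than ``tol`` or ``max_iter`` is reached. The total
        log-likelihood is non-decreasing across iterations.
        """
        models = list(self.models)
        ll_old = self.loglikelihood(models)
        trajectory = [ll_old]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            gamma = _posterior_matrix(self._arrays, models)
            models = [replace(m, slope=self._m_step_slope(m, gamma[:, k]))
                      for k, m in enumerate(models)]
            ll_new = self.loglikelihood(models)
            if ll_new < ll_old - 1e-9:
                raise RuntimeError(
                    "EM log-likelihood decreased "
                    f"({ll_old:.10g} -> {ll_new:.10g})")
            trajectory.append(ll_new)
            if ll_new - ll_old < tol:
                converged = True
                break
            ll_old = ll_new
        if not converged:
            warnings.warn(f"EM did not converge in {max_iter} iterations")
        order = np.argsort([-m.slope for m in models])
        models = [models[k] for k in order]
        gamma = _posterior_matrix(self._arrays, models)
        return LineModelMixtureResults(
            model=self, models=models, loglik=trajectory[-1],
            responsibilities=gamma, n_iter=n_iter, converged=converged,
            loglik_trajectory=trajectory)


@dataclass
class LineModelMixtureResults:
    """EM-fitted line-model mixture.

    Attributes
    ----------
    models : list of LineModel
        Classes with fitted slopes, sorted by slope descending (labels
        preserved).
    loglik : float
        Total log marginal likelihood at the optimum.
    responsibilities : numpy.ndarray
        n_variants x n_classes membership posterior matrix.
    """

    model: LineModelMixture
    models: list[LineModel]
    loglik: float
    responsibilities: np.ndarray
    n_iter: int
    converged: bool
    loglik_trajectory: list

    @property
    def slopes(self) -> dict:
        return {m.label: m.slope for m in self.models}

    def posteriors(self) -> pd.DataFrame:
        """Per-variant membership posteriors as a DataFrame."""
        out = pd.DataFrame(self.responsibilities,
                           columns=[m.label for m in self.models])
        out.insert(0, "variant_id", self.model.data["variant_id"])
        return out

    def classify(self, threshold: float = 0.95) -> pd.DataFrame:
        """Threshold posteriors into class assignments; see :func:`classify`."""
        return classify(self.model.data, self.models, threshold=threshold)

    def summary(self) -> str:
        lines = ["Line-model mixture (EM)", "=" * 46]
        for m in self.models:
            lines.append(
                f"class {m.label:<6} slope {m.slope:>9.4f}  "
                f"scale {m.scale:.3g}  cor {m.cor:.3g}  "
                f"weight {m.prior_weight:.3g}")
        lines += [
            f"{'log marginal likelihood':<28}{self.loglik:>18.6f}",
            f"{'EM iterations':<28}{self.n_iter:>18d}",
            f"{'converged':<28}{str(self.converged):>18}",
        ]
        return "\n".join(lines)


def fit_slopes_em(pairs: PairsLike, models: list[LineModel],
                  tol: float = 1e-8, max_iter: int = 1000
                  ) -> LineModelMixtureResults:
    """EM slope estimation; convenience wrapper over :class:`LineModelMixture`."""
    return LineModelMixture(pairs, models).fit(tol=tol, max_iter=max_iter)


def log10_bayes_factor(pairs: PairsLike,
                       models_two: "list[LineModel] | LineModelMixtureResults",
                       models_one: "list[LineModel] | LineModelMixtureResults",
                       ) -> float:
    """log10 Bayes factor of a two-class vs a one-class line-model fit.

    Computed as the difference of maximized total log10 mixture marginal
    likelihoods (slopes plugged in at their EM optima; no integration over
    slope uncertainty). Positive values favor the two-class model.
    """
    def total(models):
        if isinstance(models, LineModelMixtureResults):
            models = models.models
        return LineModelMixture(pairs, models).loglikelihood()

    return (total(models_two) - total(models_one)) / np.log(10.0)


def classify(pairs: PairsLike, models: list[LineModel],
             threshold: float = 0.95) -> pd.DataFrame:
    """Assign each variant to its maximum-posterior class, or "unassigned".

    A variant is assigned only when its largest membership posterior
    reaches ``threshold`` (default 0.95, the confident-assignment cut used
    for the class-G/class-T split).
    """
    df, arrays = _pair_arrays(pairs)
    post = _posterior_matrix(arrays, models)
    labels = np.array([m.label for m in models])
    best = post.argmax(axis=1)
    assigned = np.where(post.max(axis=1) >= threshold, labels[best],
                        "unassigned")
    out = pd.DataFrame(post, columns=labels)
    out.insert(0, "variant_id", df["variant_id"])
    out["assigned_label"] = assigned
    return out
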