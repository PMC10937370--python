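"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from crosstrait import EffectSimConfig, LineModel, simulate_effect_pairs
from crosstrait.linemodels import prior_covariance


def grid_search_slope(pairs: pd.DataFrame, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force minimizer of the York objective S(b) on a uniform grid.

    Independent of the fitting code: evaluates S at every grid point and
    returns (argmin, min). Used as the oracle for the slope estimate.
    """
    b = np.arange(lo, hi + step / 2, step)[:, None]
    x = pairs["beta_x"].to_numpy()[None, :]
    y = pairs["beta_y"].to_numpy()[None, :]
    sx = pairs["se_x"].to_numpy()[None, :]
    sy = pairs["se_y"].to_numpy()[None, :]
    r = pairs["r_est"].to_numpy()[None, :]
    v = sy**2 + b**2 * sx**2 - 2.0 * b * r * sx * sy
    S = np.sum((y - b * x) ** 2 / v, axis=1)
    i = int(S.argmin())
    return float(b[i, 0]), float(S[i])


def quadrature_marginal(pair, model: LineModel, half_width=1.5, n=1501):
    """Marginal likelihood by direct 2-D quadrature of the defining integral.

    Numerically integrates N(beta_hat | beta, S) * N(beta | 0, Sigma) over
    a uniform [-half_width, half_width]^2 grid of true effects with the
    trapezoid rule. Independent of the closed-form convolution used by the
    implementation.
    """
    Sigma = prior_covariance(model)
    S = pair.sampling_cov
    g = np.linspace(-half_width, half_width, n)
    B1, B2 = np.meshgrid(g, g, indexing="ij")

    def mvn_pdf(d1, d2, C):
        det = C[0, 0] * C[1, 1] - C[0, 1] ** 2
        quad = (C[1, 1] * d1**2 - 2 * C[0, 1] * d1 * d2
                + C[0, 0] * d2**2) / det
        return np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(det))

    lik = mvn_pdf(pair.beta_x - B1, pair.beta_y - B2, S)
    prior = mvn_pdf(B1, B2, Sigma)
    h = g[1] - g[0]
    return float(np.trapezoid(np.trapezoid(lik * prior, dx=h), dx=h))


@pytest.fixture(scope="session")
def five_pairs_single_class():
    """Five seeded pairs from a single line-model class with slope 0.7."""
    cfg = EffectSimConfig(
        n_variants=5,
        classes=(LineModel("A", slope=0.7, scale=0.2, cor=0.99,
                           prior_weight=1.0),),
        se_range_x=(0.01, 0.05), se_range_y=(0.01, 0.05), seed=1)
    pairs, _, _ = simulate_effect_pairs(cfg)
    return pairs


@pytest.fixture(scope="session")
def two_class_pairs_seed11():
    """300 pairs from two classes (slopes 1.5 and 0.25), seed 11."""
    cfg = EffectSimConfig(
        n_variants=300,
        classes=(LineModel("T", slope=1.5, scale=0.2, cor=0.99,
                           prior_weight=0.5),
                 LineModel("G", slope=0.25, scale=0.2, cor=0.99,
                           prior_weight=0.5)),
        se_range_x=(0.01, 0.05), se_range_y=(0.01, 0.05), seed=11)
    pairs, labels, true = simulate_effect_pairs(cfg)
    return pairs, labels, true


@pytest.fixture(scope="session")
def paper_models():
    """The two fitted line models of the GDM/T2D application."""
    return [LineModel("G", slope=0.25, scale=0.2, cor=0.99,
                      prior_weight=0.5),
            LineModel("T", slope=1.53, scale=0.2, cor=0.99,
                      prior_weight=0.5)]
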