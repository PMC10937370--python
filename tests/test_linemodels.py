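"""Line-model priors, marginal likelihoods, posteriors, EM and Bayes factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstrait import (EffectPair, EffectSimConfig, LineModel,
                        LineModelMixture, class_posteriors, classify,
                        fit_slopes_em, log10_bayes_factor, marginal_loglik,
                        prior_covariance, simulate_effect_pairs)
from conftest import quadrature_marginal


class TestPriorCovariance:
    def test_degenerate_line_limit(self):
        cov = prior_covariance(LineModel("L", slope=1.0, scale=1.0, cor=1.0))
        assert np.allclose(cov, [[1, 1], [1, 1]])
        assert np.linalg.matrix_rank(cov) == 1

    def test_direct_substitution(self):
        cov = prior_covariance(LineModel("G", slope=0.25, scale=0.2,
                                         cor=0.99))
        assert np.allclose(cov, [[0.04, 0.0099], [0.0099, 0.0025]])

    def test_determinant_identity(self):
        m = LineModel("T", slope=1.53, scale=0.2, cor=0.99)
        cov = prior_covariance(m)
        expected = m.slope**2 * m.scale**4 * (1 - m.cor**2)
        assert np.linalg.det(cov) == pytest.approx(expected)

    def test_principal_axis_aligns_with_line(self):
        m = LineModel("T", slope=1.53, scale=0.2, cor=0.99)
        vals, vecs = np.linalg.eigh(prior_covariance(m))
        principal = vecs[:, np.argmax(vals)]
        direction = np.array([1.0, 1.53])
        direction /= np.linalg.norm(direction)
        angle = np.degrees(np.arccos(np.clip(
            abs(principal @ direction), -1, 1)))
        assert angle < 1.0

    @pytest.mark.parametrize("kwargs", [
        {"slope": np.inf}, {"scale": 0.0}, {"cor": 1.5},
        {"prior_weight": -0.1}])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(label="X", slope=1.0, scale=0.2, cor=0.99,
                    prior_weight=0.5)
        with pytest.raises(ValueError):
            LineModel(**{**base, **kwargs})


class TestMarginalLoglik:
    def test_density_at_the_mean(self):
        m = LineModel("G", slope=0.25, scale=0.2, cor=0.99)
        pair = EffectPair("v", 0.0, 0.05, 0.0, 0.05)
        total = prior_covariance(m) + pair.sampling_cov
        expected = -np.log(2 * np.pi) - 0.5 * np.log(np.linalg.det(total))
        assert marginal_loglik(pair, m) == pytest.approx(expected,
                                                         abs=1e-12)

    def test_agrees_with_scipy_mvn(self):
        m = LineModel("T", slope=1.53, scale=0.2, cor=0.99)
        pair = EffectPair("v", 0.12, 0.02, 0.17, 0.03, 0.2)
        total = prior_covariance(m) + pair.sampling_cov
        expected = stats.multivariate_normal([0, 0], total).logpdf(
            [pair.beta_x, pair.beta_y])
        assert marginal_loglik(pair, m) == pytest.approx(expected,
                                                         abs=1e-12)

    @pytest.mark.parametrize("slope", [0.25, 1.53])
    def test_matches_quadrature_of_marginalization_integral(self, slope):
        """The closed form equals direct 2-D quadrature of
        integral N(beta_hat | beta, S) N(beta | 0, Sigma) dbeta."""
        m = LineModel("M", slope=slope, scale=0.2, cor=0.9)
        pair = EffectPair("v", 0.08, 0.05, 0.1, 0.05)
        oracle = np.log(quadrature_marginal(pair, m))
        assert marginal_loglik(pair, m) == pytest.approx(oracle, abs=1e-4)

    def test_r_est_sign_irrelevant_on_axes_with_diagonal_prior(self):
        m = LineModel("M", slope=1.0, scale=0.2, cor=0.0)
        a = EffectPair("v", 0.3, 0.05, 0.0, 0.05, r_est=0.4)
        b = EffectPair("v", 0.3, 0.05, 0.0, 0.05, r_est=-0.4)
        assert marginal_loglik(a, m) == pytest.approx(
            marginal_loglik(b, m), abs=1e-12)


class TestClassPosteriors:
    def test_worked_example_map3k15(self, paper_models):
        """The rare missense GDM lead (beta = -0.404, se = 0.0638) with
        its modest protective T2D effect (beta = -0.09, se recovered from
        P = 1.8e-3) lands in the GDM-predominant class with posterior
        above 0.999."""
        se_t2d = 0.09 / stats.norm.isf(1.8e-3 / 2)
        pair = EffectPair("rs56381411", -0.404, 0.0638, -0.09, se_t2d)
        post = class_posteriors(pair, paper_models)
        assert post["G"] > 0.999
        assert post["G"] + post["T"] == pytest.approx(1.0, abs=1e-9)

    def test_mirror_classes_split_evenly_on_axis(self):
        models = [LineModel("up", 1.0, 0.2, 0.9, 0.5),
                  LineModel("down", -1.0, 0.2, 0.9, 0.5)]
        pair = EffectPair("v", 0.3, 0.05, 0.0, 0.05)
        post = class_posteriors(pair, models)
        assert post["up"] == pytest.approx(0.5, abs=1e-9)

    def test_posteriors_match_normalized_quadrature(self):
        models = [LineModel("G", 0.25, 0.2, 0.9, 0.5),
                  LineModel("T", 1.53, 0.2, 0.9, 0.5)]
        rng = np.random.default_rng(3)
        for _ in range(10):
            pair = EffectPair("v", rng.normal(0, 0.2), 0.05,
                              rng.normal(0, 0.2), 0.05)
            post = class_posteriors(pair, models)
            q = np.array([quadrature_marginal(pair, m) for m in models])
            expected = 0.5 * q / (0.5 * q).sum()
            assert post["G"] == pytest.approx(expected[0], abs=1e-4)

    def test_relabeling_permutes_posteriors(self, paper_models):
        pair = EffectPair("v", 0.1, 0.02, 0.05, 0.02)
        post = class_posteriors(pair, paper_models)
        post_swapped = class_posteriors(pair, paper_models[::-1])
        assert post["G"] == pytest.approx(post_swapped["G"], abs=1e-12)

    def test_on_line_pair_gets_posterior_one_in_tight_limit(self):
        models = [LineModel("A", 2.0, 0.2, 1 - 1e-9, 0.5),
                  LineModel("B", 0.2, 0.2, 1 - 1e-9, 0.5)]
        pair = EffectPair("v", 0.1, 1e-6, 0.2, 1e-6)
        post = class_posteriors(pair, models)
        assert post["A"] == pytest.approx(1.0, abs=1e-9)

    def test_underflow_returns_uniform_with_warning(self, paper_models):
        pair = EffectPair("v", 1e200, 1e-3, -1e200, 1e-3)
        with pytest.warns(UserWarning, match="underflow"):
            post = class_posteriors(pair, paper_models)
        assert post["G"] == pytest.approx(0.5)


class TestEM:
    def test_noiseless_single_line_recovers_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.2, 50)
        pairs = pd.DataFrame({
            "beta_x": x, "se_x": 0.01,
            "beta_y": 0.5 * x, "se_y": 0.01})
        fit = fit_slopes_em(pairs, [LineModel("A", 1.0, 0.2, 0.99, 1.0)])
        assert fit.slopes["A"] == pytest.approx(0.5, abs=0.01)

    def test_two_class_recovery_within_tolerance(self,
                                                 two_class_pairs_seed11):
        pairs, _, _ = two_class_pairs_seed11
        init = [LineModel("T", 1.0, 0.2, 0.99, 0.5),
                LineModel("G", 0.2, 0.2, 0.99, 0.5)]
        fit = fit_slopes_em(pairs, init)
        assert fit.converged
        assert fit.slopes["T"] == pytest.approx(1.5, abs=0.1)
        assert fit.slopes["G"] == pytest.approx(0.25, abs=0.1)

    def test_loglik_monotone_and_slopes_sorted(self,
                                               two_class_pairs_seed11):
        pairs, _, _ = two_class_pairs_seed11
        init = [LineModel("T", 1.0, 0.2, 0.99, 0.5),
                LineModel("G", 0.2, 0.2, 0.99, 0.5)]
        fit = LineModelMixture(pairs, init).fit()
        diffs = np.diff(fit.loglik_trajectory)
        assert np.all(diffs >= -1e-9)
        slopes = [m.slope for m in fit.models]
        assert slopes == sorted(slopes, reverse=True)

    def test_responsibilities_rows_sum_to_one(self, two_class_pairs_seed11):
        pairs, _, _ = two_class_pairs_seed11
        fit = fit_slopes_em(pairs, [LineModel("T", 1.0, 0.2, 0.99, 0.5),
                                    LineModel("G", 0.2, 0.2, 0.99, 0.5)])
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0,
                           atol=1e-9)


class TestBayesFactor:
    def test_identical_model_sets_give_zero(self, two_class_pairs_seed11):
        pairs, _, _ = two_class_pairs_seed11
        one = LineModel("A", 0.7, 0.2, 0.99, 1.0)
        duplicated = [LineModel("A1", 0.7, 0.2, 0.99, 0.5),
                      LineModel("A2", 0.7, 0.2, 0.99, 0.5)]
        assert log10_bayes_factor(pairs, duplicated, [one]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_two_distinct_classes_usually_favored(self):
        """On data truly generated from two classes the two-class fit
        wins (positive log10 BF) in at least 95 of 100 replicates."""
        wins = 0
        for seed in range(1, 101):
            cfg = EffectSimConfig(
                n_variants=300,
                classes=(LineModel("T", 1.5, 0.2, 0.99, 0.5),
                         LineModel("G", 0.25, 0.2, 0.99, 0.5)),
                se_range_x=(0.01, 0.05), se_range_y=(0.01, 0.05),
                seed=seed)
            pairs, _, _ = simulate_effect_pairs(cfg)
            two = fit_slopes_em(pairs, [LineModel("T", 1.0, 0.2, 0.99, 0.5),
                                        LineModel("G", 0.2, 0.2, 0.99, 0.5)])
            one = fit_slopes_em(pairs, [LineModel("S", 0.7, 0.2, 0.99, 1.0)])
            wins += log10_bayes_factor(pairs, two, one) > 0
        assert wins >= 95


class TestClassify:
    def test_threshold_assignment(self, paper_models):
        pairs = pd.DataFrame({
            "variant_id": ["clear_G", "ambiguous"],
            "beta_x": [-0.404, 0.02], "se_x": [0.0638, 0.05],
            "beta_y": [-0.09, 0.02], "se_y": [0.0288, 0.05],
            "r_est": 0.0})
        out = classify(pairs, paper_models, threshold=0.95)
        assert out.loc[0, "assigned_label"] == "G"
        assert out.loc[1, "assigned_label"] == "unassigned"

    def test_assigned_iff_max_posterior_reaches_threshold(self,
                                                          paper_models):
        cfg = EffectSimConfig(n_variants=200, seed=9)
        pairs, _, _ = simulate_effect_pairs(cfg)
        out = classify(pairs, paper_models, threshold=0.95)
        maxp = out[["G", "T"]].max(axis=1)
        assert ((out["assigned_label"] != "unassigned")
                == (maxp >= 0.95)).all()

    def test_confident_assignments_recover_planted_labels(self):
        """Among variants confidently assigned (posterior >= 0.95) on
        well-separated two-class data with small standard errors, at
        least 99% carry their true class label."""
        cfg = EffectSimConfig(n_variants=2000,
                              se_range_x=(0.005, 0.02),
                              se_range_y=(0.005, 0.02), seed=42)
        pairs, labels, _ = simulate_effect_pairs(cfg)
        out = classify(pairs, list(cfg.classes), threshold=0.95)
        assigned = out["assigned_label"].to_numpy()
        mask = assigned != "unassigned"
        assert mask.mean() > 0.5
        assert (assigned[mask] == labels[mask]).mean() >= 0.99
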