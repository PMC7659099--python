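"""Density, posterior and fit-index computations checked against independent
multivariate-normal oracles and closed forms."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from growthmix import (
    GMMParameters,
    LongitudinalDataset,
    SCHEMES,
    build_design_matrices,
    class_conditional_loglik,
    count_free_parameters,
    fit_indices,
    marginal_covariance,
    mixture_loglik,
    posterior_probs,
    scenario_parameters,
)


def _random_params(rng, K=2, T=5, spread=2.0):
    beta = rng.normal(0, spread, size=(K, 2))
    psi = np.zeros((K, 2, 2))
    for k in range(K):
        a = rng.normal(0, 0.5, size=(2, 2))
        psi[k] = a @ a.T + 0.05 * np.eye(2)
    theta = rng.uniform(0.2, 1.5, size=(K, T))
    pi = rng.dirichlet(np.ones(K))
    return GMMParameters(pi, beta, psi, theta)


def _oracle_loglik(data, params):
    """Dense multivariate-normal densities computed via scipy, subsetting
    rows/columns of the assembled covariance for missing cells."""
    X, Z = build_design_matrices(data.time_scores, params.n_growth_terms)
    out = np.empty((data.n_subjects, params.n_classes))
    for i in range(data.n_subjects):
        o = np.flatnonzero(data.observed_mask[i])
        for k in range(params.n_classes):
            sigma = Z @ params.re_cov[k] @ Z.T + np.diag(params.residual_vars[k])
            out[i, k] = multivariate_normal.logpdf(
                data.outcomes[i, o], mean=(X @ params.fixed_effects[k])[o],
                cov=sigma[np.ix_(o, o)],
            )
    return out


class TestDesignMatrices:
    def test_linear_coding(self):
        X, Z = build_design_matrices(np.arange(5.0), 2)
        assert np.array_equal(X[:, 1], np.arange(5.0))
        assert np.array_equal(X[:, 0], np.ones(5))

    def test_polynomial_powers(self):
        X, _ = build_design_matrices(np.array([0.0, 0.5, 1.0]), 3)
        assert np.allclose(X[1], [1.0, 0.5, 0.25])

    def test_z_is_first_two_columns(self):
        X, Z = build_design_matrices(np.array([0.0, 1.0, 3.0, 7.0]), 4)
        assert np.array_equal(Z, X[:, :2])

    def test_rank_deficiency_error(self):
        with pytest.raises(ValueError, match="rank"):
            build_design_matrices(np.array([0.0, 1.0]), 3)


class TestMarginalCovariance:
    def test_pure_residual_identity(self):
        _, Z = build_design_matrices(np.arange(5.0), 2)
        sigma = marginal_covariance(np.zeros((2, 2)), np.ones(5), Z)
        assert np.allclose(sigma, np.eye(5))

    def test_scenario1_class1_diagonal(self):
        # scenario-1 class-1: intercept SD 0.3, slope SD 0.1, theta starts at 0.25
        _, Z = build_design_matrices(np.arange(5.0), 2)
        psi = np.diag([0.09, 0.01])
        theta = np.array([0.25, 0.25, 0.5, 0.5, 0.5])
        sigma = marginal_covariance(psi, theta, Z)
        assert sigma[0, 0] == pytest.approx(0.09 + 0.25)
        # corner entry: psi_I + 4 * psi_IS with psi_IS = 0
        assert sigma[0, 4] == pytest.approx(0.09)

    def test_nonfinite_rejected(self):
        _, Z = build_design_matrices(np.arange(3.0), 2)
        with pytest.raises(ValueError):
            marginal_covariance(np.full((2, 2), np.nan), np.ones(3), Z)


class TestClassConditionalLoglik:
    def test_standard_normal_at_mode(self):
        T = 4
        data = LongitudinalDataset(np.zeros((3, T)), np.arange(float(T)))
        params = GMMParameters(
            [1.0], np.zeros((1, 2)), np.zeros((1, 2, 2)), np.ones((1, T))
        )
        ll = class_conditional_loglik(data, params)
        assert np.allclose(ll, -T / 2 * np.log(2 * np.pi))

    def test_matches_mvn_oracle(self, rng):
        data = LongitudinalDataset(rng.normal(size=(5, 5)), np.arange(5.0))
        params = _random_params(rng, K=3)
        assert np.allclose(
            class_conditional_loglik(data, params), _oracle_loglik(data, params),
            atol=1e-9,
        )

    def test_missing_marginalization(self, rng):
        """Masking occasions 2 and 4 gives the 3-dimensional marginal density."""
        y = rng.normal(size=(4, 5))
        y_missing = y.copy()
        y_missing[:, [1, 3]] = np.nan
        data = LongitudinalDataset(y_missing, np.arange(5.0))
        params = _random_params(rng, K=2)
        assert np.allclose(
            class_conditional_loglik(data, params), _oracle_loglik(data, params),
            atol=1e-9,
        )


class TestMixtureLoglik:
    def test_identical_classes_collapse_to_single(self, tiny_dataset):
        one = _random_params(np.random.default_rng(0), K=1)
        two = GMMParameters(
            [0.5, 0.5],
            np.repeat(one.fixed_effects, 2, axis=0),
            np.repeat(one.re_cov, 2, axis=0),
            np.repeat(one.residual_vars, 2, axis=0),
        )
        assert mixture_loglik(tiny_dataset, two) == pytest.approx(
            mixture_loglik(tiny_dataset, one), abs=1e-10
        )

    def test_label_switching_invariance(self, tiny_dataset, rng):
        params = _random_params(rng, K=3)
        ll = mixture_loglik(tiny_dataset, params)
        for order in ([1, 2, 0], [2, 0, 1], [2, 1, 0]):
            assert mixture_loglik(tiny_dataset, params.permuted(order)) == pytest.approx(
                ll, abs=1e-10
            )

    def test_matches_bruteforce_sum(self, rng):
        data = LongitudinalDataset(rng.normal(size=(3, 5)), np.arange(5.0))
        params = _random_params(rng, K=2)
        dens = np.exp(_oracle_loglik(data, params))
        expected = np.log(dens @ params.class_probs).sum()
        assert mixture_loglik(data, params) == pytest.approx(expected, abs=1e-9)


class TestPosteriors:
    def test_identical_classes_give_prior(self, tiny_dataset):
        one = _random_params(np.random.default_rng(3), K=1)
        pi = np.array([0.3, 0.7])
        two = GMMParameters(
            pi,
            np.repeat(one.fixed_effects, 2, axis=0),
            np.repeat(one.re_cov, 2, axis=0),
            np.repeat(one.residual_vars, 2, axis=0),
        )
        post = posterior_probs(tiny_dataset, two)
        assert np.allclose(post, pi)

    def test_rows_sum_to_one_and_bayes_rule(self, rng):
        data = LongitudinalDataset(rng.normal(size=(1, 5)), np.arange(5.0))
        params = _random_params(rng, K=2)
        post = posterior_probs(data, params)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
        dens = np.exp(_oracle_loglik(data, params))[0]
        expected = params.class_probs * dens / (params.class_probs @ dens)
        assert np.allclose(post[0], expected, atol=1e-10)


class TestParameterCounting:
    @pytest.mark.parametrize(
        "scheme_id,expected",
        [("M0", 32), ("M1A", 20), ("M1B", 22), ("M1C", 26), ("M2A", 18), ("M2B", 14), ("M2C", 16)],
    )
    def test_counts_K3_T5_P2(self, scheme_id, expected):
        assert count_free_parameters(SCHEMES[scheme_id], 3, 5, 2) == expected

    @pytest.mark.parametrize("scheme_id", list(SCHEMES))
    def test_tying_matches_count(self, scheme_id):
        """Distinct values in tied theta/psi equal the counting assumptions."""
        from growthmix.estimation import _apply_ties

        scheme = SCHEMES[scheme_id]
        # all-distinct inputs so tied blocks are countable without collisions
        theta0 = (0.1 + 0.07 * np.arange(15)).reshape(3, 5)
        psi0 = np.array([np.diag([v, v / 3]) for v in (0.5, 0.9, 1.4)])
        pi0 = np.full(3, 1 / 3)
        beta0 = np.zeros((3, 2))
        _, _, psi, theta = _apply_ties(pi0, beta0, psi0, theta0, scheme, np.ones(3))
        n_theta = len(np.unique(theta.round(12)))
        expect_theta = (1 if scheme.residual_tied_over_classes else 3) * (
            1 if scheme.residual_tied_over_time else 5
        )
        assert n_theta == expect_theta
        n_psi = len({psi[k].tobytes() for k in range(3)})
        assert n_psi == (1 if scheme.random_effects_tied_over_classes else 3)


class TestFitIndices:
    def test_abic_vanishes_at_n22(self):
        out = fit_indices(-123.4, 10, 22, np.full((22, 2), 0.5))
        assert out["aBIC"] == pytest.approx(2 * 123.4)

    def test_entropy_extremes(self):
        degenerate = np.eye(3)[np.array([0, 1, 2, 0, 1])]
        assert fit_indices(-1.0, 2, 5, degenerate)["entropy"] == pytest.approx(1.0)
        uniform = np.full((5, 3), 1 / 3)
        assert fit_indices(-1.0, 2, 5, uniform)["entropy"] == pytest.approx(0.0)

    def test_entropy_in_unit_interval(self, rng):
        p = rng.dirichlet(np.ones(3), size=50)
        e = fit_indices(-10.0, 4, 50, p)["entropy"]
        assert 0.0 <= e <= 1.0

    def test_one_class_entropy_convention(self):
        assert fit_indices(-5.0, 3, 10, np.ones((10, 1)))["entropy"] == 1.0

    def test_nonfinite_loglik_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(np.nan, 2, 10, np.ones((10, 1)))
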