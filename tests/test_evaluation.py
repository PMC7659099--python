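"""Class linking, bias and accuracy, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from growthmix import (
    ClassLinking,
    FittedModel,
    GMMParameters,
    NotRecoveredError,
    SCHEMES,
    classification_accuracy,
    link_classes,
    relative_bias,
    select_best_model,
    scenario_parameters,
)


def _posteriors_from_modal(modal, K, p=0.9):
    post = np.full((len(modal), K), (1 - p) / (K - 1))
    post[np.arange(len(modal)), modal] = p
    return post


def _brute_force_matching(confusion):
    """Best one-to-one matching by exhaustive permutation search."""
    K = confusion.shape[0]
    best, best_perm = -1, None
    for perm in itertools.permutations(range(K)):
        tot = sum(confusion[i, perm[i]] for i in range(K))
        if tot > best:
            best, best_perm = tot, perm
    return best, best_perm


class TestLinkClasses:
    def test_diagonal_confusion_identity(self):
        labels = np.repeat([1, 2, 3], 100)
        post = _posteriors_from_modal(np.repeat([0, 1, 2], 100), 3)
        link = link_classes(labels, post)
        assert link.recovered
        assert np.array_equal(link.mapping, [0, 1, 2])
        assert np.array_equal(link.confusion, np.diag([100, 100, 100]))

    def test_two_classes_collapsed_not_recovered(self):
        # simulated classes 1 and 2 both majority-assigned to estimated class 0
        labels = np.repeat([1, 2, 3], 50)
        modal = np.r_[np.zeros(50, int), np.zeros(45, int), np.ones(5, int), np.full(50, 2)]
        link = link_classes(labels, _posteriors_from_modal(modal, 3))
        assert not link.recovered

    def test_exactly_half_is_not_recovery(self):
        labels = np.repeat([1, 2], 10)
        modal = np.r_[np.zeros(5, int), np.ones(5, int), np.ones(10, int)]
        link = link_classes(labels, _posteriors_from_modal(modal, 2))
        assert not link.recovered  # strict majority required

    def test_nan_posteriors_not_recovered(self):
        labels = np.array([1, 2, 1, 2])
        post = np.full((4, 2), np.nan)
        assert not link_classes(labels, post).recovered

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_matches_exhaustive_permutation_oracle(self, K, rng):
        for _ in range(30):
            n = 60
            labels = rng.integers(1, K + 1, size=n)
            # make sure every simulated class occurs
            labels[:K] = np.arange(1, K + 1)
            modal = rng.integers(0, K, size=n)
            link = link_classes(labels, _posteriors_from_modal(modal, K))
            best, _ = _brute_force_matching(link.confusion)
            got = link.confusion[np.arange(K), link.mapping].sum()
            assert got == best


class TestRelativeBias:
    def test_exact_estimates_zero_bias(self):
        pop = scenario_parameters(1, "low")
        link = ClassLinking(np.arange(3), True, np.diag([10, 10, 10]))
        tab = relative_bias(pop, pop, link)
        assert np.allclose(tab.bias, 0.0)

    def test_zero_true_value_uses_absolute_bias(self):
        pop = scenario_parameters(1, "low")  # class-1 slope is exactly 0
        est = GMMParameters(
            pop.class_probs, pop.fixed_effects.copy(), pop.re_cov, pop.residual_vars
        )
        est.fixed_effects[0, 1] = 0.05
        link = ClassLinking(np.arange(3), True, np.diag([10, 10, 10]))
        tab = relative_bias(pop, est, link)
        row = tab[(tab["class"] == 1) & (tab.parameter == "slope")].iloc[0]
        assert row.bias == pytest.approx(0.05)
        assert not row.relative

    def test_class3_slope_arithmetic(self):
        pop = scenario_parameters(1, "low")
        est = GMMParameters(
            pop.class_probs, pop.fixed_effects.copy(), pop.re_cov, pop.residual_vars
        )
        est.fixed_effects[2, 1] = 0.39  # true 0.30
        link = ClassLinking(np.arange(3), True, np.diag([10, 10, 10]))
        tab = relative_bias(pop, est, link)
        row = tab[(tab["class"] == 3) & (tab.parameter == "slope")].iloc[0]
        assert row.bias == pytest.approx(0.3)

    def test_respects_linking_map(self):
        pop = scenario_parameters(1, "low")
        est = pop.permuted([2, 0, 1])  # estimated class order scrambled
        mapping = np.empty(3, dtype=int)
        mapping[[2, 0, 1]] = np.arange(3)
        link = ClassLinking(mapping, True, np.diag([10, 10, 10]))
        tab = relative_bias(pop, est, link)
        assert np.allclose(tab.bias, 0.0)

    def test_scale_consistency(self):
        pop = scenario_parameters(1, "low")
        est = GMMParameters(
            pop.class_probs, pop.fixed_effects * 1.07, pop.re_cov, pop.residual_vars
        )
        doubled_pop = GMMParameters(
            pop.class_probs, pop.fixed_effects * 2, pop.re_cov, pop.residual_vars
        )
        doubled_est = GMMParameters(
            pop.class_probs, est.fixed_effects * 2, pop.re_cov, pop.residual_vars
        )
        link = ClassLinking(np.arange(3), True, np.diag([10, 10, 10]))
        a = relative_bias(pop, est, link)
        b = relative_bias(doubled_pop, doubled_est, link)
        rel = a.relative.to_numpy()
        assert np.allclose(a.bias[rel], b.bias[rel])

    def test_undefined_without_recovery(self):
        pop = scenario_parameters(1, "low")
        link = ClassLinking(np.arange(3), False, np.zeros((3, 3), int))
        with pytest.raises(NotRecoveredError):
            relative_bias(pop, pop, link)


class TestClassificationAccuracy:
    def test_perfect_posteriors(self):
        labels = np.repeat([1, 2, 3], 20)
        post = _posteriors_from_modal(np.repeat([0, 1, 2], 20), 3, p=0.99)
        link = link_classes(labels, post)
        assert classification_accuracy(labels, post, link) == 1.0

    def test_matches_naive_count(self, rng):
        labels = rng.integers(1, 4, size=200)
        labels[:3] = [1, 2, 3]
        post = rng.dirichlet(np.ones(3) * 0.5, size=200)
        link = link_classes(labels, post)
        if not link.recovered:
            link = ClassLinking(link.mapping, True, link.confusion)
        acc = classification_accuracy(labels, post, link)
        count = sum(
            int(np.argmax(post[i]) == link.mapping[labels[i] - 1]) for i in range(200)
        )
        assert acc == pytest.approx(count / 200)

    def test_invariant_to_simultaneous_relabeling(self, rng):
        labels = np.repeat([1, 2, 3], 30)
        post = rng.dirichlet(np.ones(3), size=90)
        link = link_classes(labels, post)
        link = ClassLinking(link.mapping, True, link.confusion)
        acc = classification_accuracy(labels, post, link)
        perm = np.array([2, 0, 1])  # estimated class j becomes perm[j]
        post_perm = post[:, np.argsort(perm)]
        link_perm = ClassLinking(perm[link.mapping], True, link.confusion)
        assert classification_accuracy(labels, post_perm, link_perm) == pytest.approx(acc)

    def test_undefined_without_recovery(self):
        link = ClassLinking(np.arange(2), False, np.zeros((2, 2), int))
        with pytest.raises(NotRecoveredError):
            classification_accuracy(np.array([1, 2]), np.eye(2), link)


def _fake_fit(scheme_id, converged=True, **indices):
    scheme = SCHEMES[scheme_id]
    from growthmix import count_free_parameters

    defaults = {"AIC": np.nan, "BIC": np.nan, "aBIC": np.nan, "entropy": np.nan}
    defaults.update(indices)
    return FittedModel(
        scheme, None, -100.0, count_free_parameters(scheme, 3, 5, 2), None,
        defaults, converged,
    )


class TestSelectBestModel:
    def test_lowest_aic_wins(self):
        fits = [_fake_fit("M0", AIC=100.0), _fake_fit("M1A", AIC=101.0)]
        assert select_best_model(fits, "AIC") == "M0"

    def test_highest_entropy_wins(self):
        fits = [_fake_fit("M0", entropy=0.6), _fake_fit("M2A", entropy=0.8)]
        assert select_best_model(fits, "entropy") == "M2A"

    def test_tie_goes_to_fewer_parameters(self):
        fits = [_fake_fit("M0", BIC=500.0), _fake_fit("M1A", BIC=500.0)]
        assert select_best_model(fits, "BIC") == "M1A"  # 20 < 32 params

    def test_nonconverged_excluded(self):
        fits = [_fake_fit("M0", AIC=90.0, converged=False), _fake_fit("M1A", AIC=101.0)]
        assert select_best_model(fits, "AIC") == "M1A"

    def test_no_converged_fits_gives_none(self):
        fits = [_fake_fit("M0", AIC=90.0, converged=False)]
        assert select_best_model(fits, "AIC") is None

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([_fake_fit("M0", AIC=1.0)], "DIC")
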