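import warnings
from itertools import permutations

import numpy as np
import pytest

from neurofuzzy.anfis import (ANFISClassifier, ANFISModel, MF, anfis_classify,
                              anfis_forward, anfis_loss, build_rule_base,
                              firing_strengths, premise_gradients, train_anfis)
from neurofuzzy.exceptions import (ConfigurationError, DegenerateInputError,
                                   NeuroFuzzyError)


def two_rule_model(f1=1.0, f2=2.0, n_heads=1):
    """1-feature model with two bell rules and constant consequents f1, f2."""
    mfs = [[MF("bell", (1.0, 2.0, 0.0)), MF("bell", (1.0, 2.0, 4.0))]]
    cons = np.zeros((2, n_heads, 2))
    cons[0, :, 1] = f1
    cons[1, :, 1] = f2
    return ANFISModel(mfs=mfs, rule_index=np.array([[0], [1]]), consequents=cons)


class TestRuleBase:
    def test_grid_size_is_cartesian_product(self, rng):
        model = build_rule_base(2, 2, rng.normal(size=(20, 2)))
        assert model.n_rules == 4

    def test_three_mfs_centered_at_min_mid_max(self):
        X = np.array([[0.0], [5.0], [10.0], [2.0]])
        model = build_rule_base(1, 3, X)
        centers = [mf.params[2] for mf in model.mfs[0]]
        assert centers == [0.0, 5.0, 10.0]

    def test_rule_cap_enforced(self, rng):
        with pytest.raises(ConfigurationError, match="cap"):
            build_rule_base(3, 3, rng.normal(size=(10, 3)), rule_cap=20)

    def test_consequents_start_at_zero(self, rng):
        model = build_rule_base(2, 2, rng.normal(size=(10, 2)), n_heads=3)
        assert np.all(model.consequents == 0)


class TestFiringStrengths:
    def test_normalised_strengths_sum_to_one(self, rng):
        model = build_rule_base(2, 3, rng.normal(size=(30, 2)))
        for x in rng.normal(size=(50, 2)):
            w, wbar = firing_strengths(model, x)
            assert wbar.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)

    def test_equal_strengths_normalise_to_half(self):
        model = two_rule_model()
        w, wbar = firing_strengths(model, np.array([2.0]))  # midpoint
        np.testing.assert_allclose(wbar, [0.5, 0.5], atol=1e-12)

    def test_single_rule_normalises_to_one(self, rng):
        model = build_rule_base(1, 1, rng.normal(size=(10, 1)))
        _, wbar = firing_strengths(model, np.array([0.3]))
        np.testing.assert_allclose(wbar, [1.0])

    def test_already_normalised_pair_is_preserved(self):
        # Gaussian rules engineered so w = (0.8, 0.2) exactly
        mfs = [[MF("gaussian", (0.0, 1.0)), MF("gaussian", (0.0, 1.0))]]
        cons = np.zeros((2, 1, 2))
        model = ANFISModel(mfs=mfs, rule_index=np.array([[0], [1]]), consequents=cons)
        w, wbar = firing_strengths(model, np.array([0.0]))
        np.testing.assert_allclose(w, [1.0, 1.0])
        np.testing.assert_allclose(wbar, [0.5, 0.5])

    def test_vanished_strengths_raise_degenerate(self):
        mfs = [[MF("gaussian", (0.0, 1e-3))]]
        model = ANFISModel(mfs=mfs, rule_index=np.array([[0]]),
                           consequents=np.zeros((1, 1, 2)))
        with pytest.raises(DegenerateInputError):
            firing_strengths(model, np.array([1e6]))


class TestForward:
    def test_equal_firing_gives_mean_of_consequents(self):
        model = two_rule_model(1.0, 2.0)
        assert anfis_forward(model, np.array([2.0]))[0] == pytest.approx(1.5)

    def test_weighted_mixture_hand_computed(self):
        """w = (0.8, 0.2) with f = (1, 2) must yield 0.8*1 + 0.2*2 = 1.2."""
        # Gaussian memberships engineered to fire at exactly 0.8 and 0.2 at x=0
        c1 = np.sqrt(-2.0 * np.log(0.8))
        c2 = np.sqrt(-2.0 * np.log(0.2))
        mfs = [[MF("gaussian", (c1, 1.0)), MF("gaussian", (c2, 1.0))]]
        cons = np.zeros((2, 1, 2))
        cons[0, 0, 1], cons[1, 0, 1] = 1.0, 2.0
        model = ANFISModel(mfs=mfs, rule_index=np.array([[0], [1]]), consequents=cons)
        x = np.array([0.0])
        w, _ = firing_strengths(model, x)
        np.testing.assert_allclose(w, [0.8, 0.2], rtol=1e-12)
        assert anfis_forward(model, x)[0] == pytest.approx(1.2, rel=1e-12)

    def test_zero_consequents_give_zero_everywhere(self, rng):
        model = build_rule_base(2, 2, rng.normal(size=(10, 2)))
        out = anfis_forward(model, rng.normal(size=(20, 2)))
        np.testing.assert_allclose(out, 0.0)

    def test_single_rule_reproduces_its_consequent(self):
        mfs = [[MF("bell", (1.0, 2.0, 0.0))]]
        cons = np.array([[[2.0, -1.0]]])  # f(x) = 2x - 1
        model = ANFISModel(mfs=mfs, rule_index=np.array([[0]]), consequents=cons)
        for x in [-3.0, 0.0, 1.7]:
            assert anfis_forward(model, np.array([x]))[0] == pytest.approx(2 * x - 1)

    def test_duplicating_the_rule_base_leaves_output_unchanged(self, rng):
        """Every strength doubles, the normalisation cancels it exactly."""
        model = two_rule_model(1.5, -0.5)
        dup = ANFISModel(
            mfs=model.mfs,
            rule_index=np.array([[0], [1], [0], [1]]),
            consequents=np.vstack([model.consequents, model.consequents]))
        X = rng.normal(size=(25, 1))
        np.testing.assert_allclose(anfis_forward(dup, X), anfis_forward(model, X),
                                   rtol=1e-12)


class TestTraining:
    def test_linear_target_solved_exactly_in_first_pass(self, rng):
        """A target that is linear in x is representable by any rule grid."""
        X = rng.normal(size=(50, 1))
        T = (3.0 * X + 1.0)
        model = build_rule_base(1, 2, X, n_heads=1)
        model, trace = train_anfis(model, X, T, epochs=1)
        assert trace[0] == pytest.approx(0.0, abs=1e-16)
        np.testing.assert_allclose(anfis_forward(model, X), T, atol=1e-8)

    def test_zero_premise_rate_keeps_premises(self, rng):
        X = rng.normal(size=(40, 1))
        T = np.tanh(X)
        model = build_rule_base(1, 2, X)
        before = [mf.params.copy() for mf in model.mfs[0]]
        model, _ = train_anfis(model, X, T, epochs=5, premise_learning_rate=0.0)
        for mf, orig in zip(model.mfs[0], before):
            np.testing.assert_array_equal(mf.params, orig)

    @pytest.mark.parametrize("family", ["bell", "gaussian"])
    def test_premise_gradient_matches_finite_differences(self, family, rng):
        X = rng.normal(size=(20, 1))
        T = rng.normal(size=(20, 2))
        model = build_rule_base(1, 2, X, n_heads=2, mf_family=family)
        from neurofuzzy.anfis import _solve_consequents
        _solve_consequents(model, X, T)
        model.consequents += rng.normal(0, 0.1, model.consequents.shape)
        grads = premise_gradients(model, X, T)
        eps = 1e-6
        for a, mf in enumerate(model.mfs[0]):
            for pi in range(mf.params.size):
                orig = mf.params[pi]
                mf.params[pi] = orig + eps
                lp = anfis_loss(model, X, T)
                mf.params[pi] = orig - eps
                lm = anfis_loss(model, X, T)
                mf.params[pi] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[0][a][pi] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_consequent_step_never_increases_loss(self, rng):
        """The LS solve is optimal: loss after it <= loss before it."""
        X = rng.normal(size=(60, 2))
        T = np.column_stack([np.sin(X[:, 0]), np.cos(X[:, 1])])
        model = build_rule_base(2, 2, X, n_heads=2)
        from neurofuzzy.anfis import _solve_consequents
        for _ in range(4):
            before = anfis_loss(model, X, T)
            _solve_consequents(model, X, T)
            after = anfis_loss(model, X, T)
            assert after <= before + 1e-10
            grads = premise_gradients(model, X, T)
            for j, g in enumerate(grads):
                for a, mf in enumerate(model.mfs[j]):
                    mf.params = mf.params - 0.01 * g[a]

    def test_underdetermined_system_warns_and_uses_ridge(self, rng):
        X = rng.normal(size=(5, 2))
        T = rng.normal(size=(5, 1))
        model = build_rule_base(2, 2, X)  # 12 consequent params > 5 samples
        with pytest.warns(RuntimeWarning, match="ridge"):
            train_anfis(model, X, T, epochs=1)


class TestClassify:
    def test_argmax_over_heads(self):
        model = two_rule_model(n_heads=2)
        model.consequents[:, 0, 1] = 0.9
        model.consequents[:, 1, 1] = 0.1
        assert anfis_classify(model, np.array([0.0])) == 0

    def test_tie_breaks_to_lowest_index(self):
        model = two_rule_model(n_heads=2)
        model.consequents[:, :, 1] = 0.5
        assert anfis_classify(model, np.array([0.0])) == 0

    def test_follows_permutation_of_heads(self, rng):
        base = np.array([0.2, 0.5, 0.8])
        for perm in permutations(range(3)):
            model = two_rule_model(n_heads=3)
            for h, p in enumerate(perm):
                model.consequents[:, h, 1] = base[p]
            assert anfis_classify(model, np.array([0.0])) == int(np.argmax(base[list(perm)]))

    def test_estimator_separates_gaussians(self, separable_dataset):
        from neurofuzzy.preprocessing import PipelineConfig, prepare
        train, test, _ = prepare(separable_dataset, PipelineConfig(seed=11))
        clf = ANFISClassifier(epochs=5).fit(train.X, train.y)
        assert (clf.predict(test.X) == test.y).mean() >= 0.95
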