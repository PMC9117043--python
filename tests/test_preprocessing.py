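import numpy as np
import pandas as pd
import pytest

from neurofuzzy.exceptions import ConfigurationError, NeuroFuzzyError
from neurofuzzy.preprocessing import (CategoricalEncoder, Dataset,
                                      PipelineConfig, encode_categoricals,
                                      impute_mean, normalize_range, prepare,
                                      select_features_correlation, split)


def ds(X, y=None, **kw):
    X = np.asarray(X, dtype=float)
    if y is None:
        y = np.zeros(X.shape[0], int)
    return Dataset(X=X, y=y, **kw)


class TestImputeMean:
    def test_missing_replaced_by_observed_mean(self):
        out = impute_mean(ds([[1.0], [np.nan], [3.0]]))
        np.testing.assert_array_equal(out.X[:, 0], [1.0, 2.0, 3.0])

    def test_no_missing_is_identity(self, rng):
        data = ds(rng.normal(size=(10, 3)))
        out = impute_mean(data)
        np.testing.assert_array_equal(out.X, data.X)

    def test_constant_column_with_missing(self):
        out = impute_mean(ds([[2.0], [2.0], [np.nan], [np.nan]]))
        np.testing.assert_array_equal(out.X[:, 0], [2.0, 2.0, 2.0, 2.0])

    def test_idempotent(self, rng):
        X = rng.normal(size=(20, 4))
        X[rng.random(X.shape) < 0.2] = np.nan
        once = impute_mean(ds(X))
        twice = impute_mean(once)
        np.testing.assert_array_equal(once.X, twice.X)

    def test_fully_missing_feature_names_the_feature(self):
        with pytest.raises(NeuroFuzzyError, match="bad"):
            impute_mean(ds(np.full((3, 1), np.nan), feature_names=["bad"]))


class TestCorrelationSelection:
    def test_exact_duplicate_dropped(self, fixtures):
        data = fixtures["duplicated_feature"]
        reduced, dropped = select_features_correlation(data, threshold=0.95)
        assert len(dropped) == 1
        assert dropped[0] in ("a", "a_copy")
        assert reduced.n_features == 2

    def test_independent_features_survive(self, rng):
        X = rng.normal(size=(200, 6))
        y = rng.integers(0, 2, 200)
        reduced, dropped = select_features_correlation(ds(X, y), threshold=0.95)
        assert dropped == []
        assert reduced.n_features == 6

    def test_threshold_one_without_duplicates_is_identity(self, rng):
        X = rng.normal(size=(50, 4))
        reduced, dropped = select_features_correlation(ds(X), threshold=1.0)
        assert dropped == []

    def test_member_less_correlated_with_class_goes(self, rng):
        signal = rng.normal(size=100)
        y = (signal > 0).astype(int)
        noisy = signal + rng.normal(0, 0.05, 100)     # high |r| with signal
        X = np.column_stack([noisy, signal])
        reduced, dropped = select_features_correlation(
            ds(X, y, feature_names=["noisy", "clean"]), threshold=0.9)
        assert dropped == ["noisy"]
        assert reduced.feature_names == ["clean"]

    def test_never_drops_both_members(self, rng):
        # three mutual near-copies: at least one survivor must remain
        base = rng.normal(size=80)
        X = np.column_stack([base, base + rng.normal(0, 0.01, 80),
                             base + rng.normal(0, 0.01, 80)])
        reduced, dropped = select_features_correlation(ds(X, (base > 0).astype(int)),
                                                       threshold=0.95)
        assert reduced.n_features >= 1
        assert reduced.n_features + len(dropped) == 3

    def test_zero_variance_feature_retained(self, rng):
        X = np.column_stack([np.full(30, 2.0), rng.normal(size=30)])
        reduced, dropped = select_features_correlation(ds(X), threshold=0.95)
        assert dropped == []


class TestNormalizeRange:
    def test_symmetric_column_maps_to_unit_interval(self):
        train, _, _ = normalize_range(ds([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(train.X[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_midpoint(self):
        train, _, _ = normalize_range(ds([[5.0], [5.0]]))
        np.testing.assert_array_equal(train.X[:, 0], [0.0, 0.0])

    def test_test_split_uses_train_parameters(self):
        train, test, _ = normalize_range(ds([[0.0], [10.0]]), ds([[10.0], [20.0]]))
        assert test.X[0, 0] == pytest.approx(1.0)   # equals train max
        assert test.X[1, 0] == pytest.approx(3.0)   # beyond the bounds: no leak
        clipped = normalize_range(ds([[0.0], [10.0]]), ds([[20.0]]), clip_test=True)[1]
        assert clipped.X[0, 0] == 1.0

    def test_custom_bounds(self):
        train, _, _ = normalize_range(ds([[0.0], [1.0]]), lo=0.0, hi=10.0)
        np.testing.assert_allclose(train.X[:, 0], [0.0, 10.0])

    def test_rejects_unimputed_data(self):
        with pytest.raises(NeuroFuzzyError):
            normalize_range(ds([[np.nan], [1.0]]))


class TestSplit:
    def test_sizes_round_fraction(self, rng):
        data = ds(rng.normal(size=(100, 2)), rng.integers(0, 2, 100))
        train, test = split(data, fraction=0.7, seed=0, stratified=False)
        assert (train.n_samples, test.n_samples) == (70, 30)

    def test_same_seed_identical_partition(self, rng):
        data = ds(rng.normal(size=(40, 2)), rng.integers(0, 2, 40))
        a = split(data, 0.7, seed=9)
        b = split(data, 0.7, seed=9)
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].y, b[1].y)

    def test_stratified_allocation_rounds_per_class(self):
        y = np.r_[np.zeros(90, int), np.ones(10, int)]
        data = ds(np.arange(100.0)[:, None], y)
        train, test = split(data, 0.7, seed=1, stratified=True)
        assert np.sum(train.y == 0) == 63 and np.sum(train.y == 1) == 7
        assert np.sum(test.y == 0) == 27 and np.sum(test.y == 1) == 3

    def test_tiny_class_absent_from_train_errors(self):
        y = np.r_[np.zeros(10, int), np.ones(1, int)]
        data = ds(np.arange(11.0)[:, None], y)
        with pytest.raises(ConfigurationError):
            split(data, 0.1, seed=0, stratified=True)


class TestEncoding:
    def test_ordinal_by_sorted_category(self):
        frame = pd.DataFrame({"flag": ["yes", "no", "yes"], "class": ["a", "b", "a"]})
        data, enc = encode_categoricals(frame)
        np.testing.assert_array_equal(data.X[:, 0], [1.0, 0.0, 1.0])  # no=0, yes=1
        np.testing.assert_array_equal(data.y, [0, 1, 0])

    def test_one_hot_indicators_sum_to_one(self):
        frame = pd.DataFrame({"color": ["r", "g", "b", "g"],
                              "class": ["x", "x", "y", "y"]})
        data, _ = encode_categoricals(frame, encoding="one_hot")
        assert data.n_features == 3
        np.testing.assert_array_equal(data.X.sum(axis=1), np.ones(4))

    def test_unseen_test_category_errors(self):
        enc = CategoricalEncoder()
        enc.fit_transform(pd.DataFrame({"c": ["a", "b"]}))
        with pytest.raises(NeuroFuzzyError, match="unseen"):
            enc.transform(pd.DataFrame({"c": ["a", "z"]}))

    def test_numeric_columns_pass_through(self):
        frame = pd.DataFrame({"v": [1.5, 2.5], "class": ["p", "q"]})
        data, _ = encode_categoricals(frame)
        np.testing.assert_array_equal(data.X[:, 0], [1.5, 2.5])

    def test_missing_class_label_rejected(self):
        frame = pd.DataFrame({"v": [1.0, 2.0], "class": ["p", None]})
        with pytest.raises(NeuroFuzzyError):
            encode_categoricals(frame)


class TestPipeline:
    def test_prepare_runs_in_order_without_leakage(self, rng):
        X = rng.normal(size=(60, 3))
        X = np.column_stack([X, X[:, 0] + rng.normal(0, 0.001, 60)])  # duplicate
        X[rng.random(X.shape) < 0.05] = np.nan
        # plant an extreme value so the overall maximum is known by construction
        X[0, 2] = 100.0
        y = rng.integers(0, 2, 60)
        data = ds(X, y)
        found_leakfree_split = False
        for seed in range(10):  # some split must place the extremum in test
            train, test, info = prepare(data, PipelineConfig(seed=seed))
            assert info["dropped_features"]          # the duplicate went
            assert not np.isnan(train.X).any() and not np.isnan(test.X).any()
            assert train.X.min() >= -1.0 and train.X.max() <= 1.0
            if test.X.max() > 1.0:
                # the planted extremum landed in test and was mapped with
                # train-only parameters: no leakage
                found_leakfree_split = True
        assert found_leakfree_split

    def test_paper_literal_order_normalises_before_split(self, rng):
        data = ds(rng.normal(size=(50, 2)), rng.integers(0, 2, 50))
        cfg = PipelineConfig(seed=0, paper_literal_order=True)
        train, test, _ = prepare(data, cfg)
        both = np.vstack([train.X, test.X])
        assert both.min() == pytest.approx(-1.0) and both.max() == pytest.approx(1.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig(norm_lo=1.0, norm_hi=-1.0)
        with pytest.raises(ConfigurationError):
            PipelineConfig(split_fraction=1.5)
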