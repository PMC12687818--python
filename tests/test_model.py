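"""SMOTE, the balanced random forest, and randomized hyperparameter search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridsurv import model
from hybridsurv.model import ForestConfig, SmoteConfig


def _imbalanced(rng, n_maj=40, n_min=12, d=3):
    X = np.vstack([rng.normal(0, 1, (n_maj, d)), rng.normal(3, 1, (n_min, d))])
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y


class TestSmote:
    def test_balances_classes(self, rng):
        X, y = _imbalanced(rng)
        Xo, yo, _ = model.smote(X, y, SmoteConfig(seed=0))
        counts = np.bincount(yo)
        assert counts[0] == counts[1]

    def test_originals_preserved_verbatim(self, rng):
        X, y = _imbalanced(rng)
        Xo, yo, _ = model.smote(X, y, SmoteConfig(seed=0))
        assert np.array_equal(Xo[: len(y)], X)
        assert np.array_equal(yo[: len(y)], y)

    def test_already_balanced_unchanged(self, rng):
        X, y = _imbalanced(rng, n_maj=10, n_min=10)
        Xo, yo, _ = model.smote(X, y)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_two_point_minority_on_segment(self, rng):
        X = np.vstack([rng.normal(5, 0.1, (6, 2)), [[0.0, 0.0], [1.0, 1.0]]])
        y = np.array([0] * 6 + [1] * 2)
        with pytest.warns(UserWarning, match="reducing k"):
            Xo, yo, _ = model.smote(X, y, SmoteConfig(seed=3))
        synth = Xo[len(y):]
        assert len(synth) == 4
        # every synthetic point lies on the segment between (0,0) and (1,1)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0) & (synth <= 1))

    def test_synthetic_between_parents_featurewise(self, rng):
        X, y = _imbalanced(rng, n_min=8)
        cfg = SmoteConfig(k_neighbors=3, seed=1)
        Xo, yo, parents = model.smote(X, y, cfg)
        minority = X[y == 1]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        synth = Xo[len(y):]
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)
        # provenance points back into the original minority rows
        assert np.all(y[parents[len(y):]] == 1)

    def test_single_member_minority_error(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match=">= 2 members"):
            model.smote(X, y)


class TestBalancedForest:
    def test_separable_data_high_accuracy(self, rng):
        n = 200
        X = np.vstack([rng.normal(-2, 1, (n // 2, 2)), rng.normal(2, 1, (n // 2, 2))])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        f = model.train_forest(X, y, ForestConfig(n_estimators=50, seed=0))
        assert np.mean(f.predict(X) == y) >= 0.99

    def test_shuffled_labels_at_chance(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.permutation([0] * 130 + [1] * 70)
        score = model._cv_macro_f1(X, y, ForestConfig(n_estimators=50, seed=0),
                                   n_splits=5, seed=0, smote_k=5)
        assert 0.35 <= score <= 0.65

    def test_deterministic_under_seed(self, rng):
        X, y = _imbalanced(rng, n_maj=60, n_min=30)
        p1 = model.train_forest(X, y, ForestConfig(n_estimators=30, seed=7)).predict_proba(X)
        p2 = model.train_forest(X, y, ForestConfig(n_estimators=30, seed=7)).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_probabilities_valid(self, rng):
        X, y = _imbalanced(rng)
        proba = model.train_forest(X, y, ForestConfig(n_estimators=20, seed=0)).predict_proba(X)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_empty_input_error(self):
        with pytest.raises(ValueError, match="empty"):
            model.train_forest(np.empty((0, 2)), np.empty(0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_balanced_bootstrap_equalizes_classes(self, seed):
        # each tree's training bootstrap holds n_min samples of every class
        rng = np.random.default_rng(seed)
        counts = np.array([17, 5])
        idx = [np.arange(counts[0]), np.arange(counts[0], counts.sum())]
        boot = np.concatenate([rng.choice(i, size=counts.min(), replace=True) for i in idx])
        labels = (boot >= counts[0]).astype(int)
        assert np.bincount(labels)[0] == np.bincount(labels)[1] == counts.min()


class TestTuning:
    def test_single_configuration_returned(self, rng):
        X, y = _imbalanced(rng, n_maj=60, n_min=30)
        domains = {"n_estimators": [50], "max_depth": [10], "max_features": ["sqrt"],
                   "min_samples_split": [2], "min_samples_leaf": [1]}
        cfg, table = model.tune_hyperparameters(X, y, domains, n_candidates=5, seed=0)
        assert cfg.n_estimators == 50 and cfg.max_depth == 10
        assert len(table) == 1

    def test_fields_within_domains(self, rng):
        X, y = _imbalanced(rng, n_maj=60, n_min=30)
        cfg, table = model.tune_hyperparameters(X, y, n_candidates=3, seed=1, n_splits=3)
        assert cfg.n_estimators in model.SEARCH_DOMAINS["n_estimators"]
        assert cfg.max_depth in model.SEARCH_DOMAINS["max_depth"]
        assert cfg.max_features in model.SEARCH_DOMAINS["max_features"]
        assert cfg.min_samples_split in model.SEARCH_DOMAINS["min_samples_split"]
        assert cfg.min_samples_leaf in model.SEARCH_DOMAINS["min_samples_leaf"]
        # argmax selection: the chosen score is the table maximum
        best = max(row["cv_macro_f1"] for row in table)
        assert any(row["cv_macro_f1"] == best for row in table)

    def test_invalid_candidate_count(self, rng):
        X, y = _imbalanced(rng)
        with pytest.raises(ValueError, match="n_candidates"):
            model.tune_hyperparameters(X, y, n_candidates=0)
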