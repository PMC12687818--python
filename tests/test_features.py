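"""Trait derivations and the preprocessing chain (pruning, filtering,
standardization, KNN imputation, stratified splitting)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridsurv import features


class TestBodyCondition:
    def test_values(self):
        assert features.body_condition(30.0, 30.0) == 1.0
        assert features.body_condition(33.0, 27.5) == pytest.approx(1.2)

    def test_guards(self):
        with pytest.raises(ValueError, match="tarsus"):
            features.body_condition(30.0, 0.0)
        assert math.isnan(features.body_condition(math.nan, 28.0))


class TestGeography:
    def test_great_circle(self):
        assert features.great_circle_km(49, -122, 49, -122) == 0.0
        assert features.great_circle_km(49, -122, 49, -121) == pytest.approx(73.1, abs=0.5)
        assert features.great_circle_km(0, 0, 0, 180) == pytest.approx(20015, abs=1)

    def test_initial_bearing(self):
        assert features.initial_bearing(50, -122, 45, -122) == pytest.approx(180.0)
        assert features.initial_bearing(49, -122, 49, -121) == pytest.approx(89.62, abs=0.05)

    @given(st.floats(-80, 80), st.floats(-170, 170), st.floats(-80, 80), st.floats(-170, 170))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bearing_range_and_mirror(self, lat1, lon1, lat2, lon2):
        theta = features.initial_bearing(lat1, lon1, lat2, lon2)
        assert 0.0 <= theta < 360.0
        # mirroring longitudes across the meridian flips east/west:
        # theta + mirrored must be 0 modulo 360 (circular distance)
        mirrored = features.initial_bearing(lat1, -lon1, lat2, -lon2)
        d = (theta + mirrored) % 360.0
        assert min(d, 360.0 - d) < 1e-6


def _det(rows):
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon", "days_since_tag"])


class TestFallBehaviour:
    release = (49.0, -122.0)

    def test_bearing_due_south(self):
        det = _det([("S1", 48.0, -122.0, 5.0)])
        assert features.fall_bearing(self.release, det) == pytest.approx(180.0)

    def test_bearing_distance_rule(self):
        # nearest detection at ~450 km -> missing
        det = _det([("S1", 45.0, -122.0, 5.0)])
        assert math.isnan(features.fall_bearing(self.release, det))

    def test_bearing_skips_coincident_station(self):
        det = _det([("S0", 49.0, -122.0, 1.0), ("S1", 48.0, -122.0, 5.0)])
        assert features.fall_bearing(self.release, det) == pytest.approx(180.0)

    def test_bearing_fall_window(self):
        # outside the fall window relative to release day 240 -> ignored
        det = _det([("S1", 48.0, -122.0, 200.0)])
        assert math.isnan(features.fall_bearing(self.release, det, release_day=240))

    def test_timing_first_within_30km(self):
        near = _det([("S1", 49.05, -122.0, 10.0)])  # ~6 km
        assert features.fall_timing(240, self.release, near) == 250
        # 40 km at day 240 does not qualify; 25 km at day 260 does
        mixed = _det([("S1", 48.64, -122.0, 0.0), ("S2", 48.80, -122.0, 20.0)])
        assert features.fall_timing(240, self.release, mixed) == 260

    def test_timing_missing(self):
        far = _det([("S1", 45.0, -122.0, 10.0)])
        assert math.isnan(features.fall_timing(240, self.release, far))


class TestCorrelationPrune:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        kept = features.correlation_prune(table, priority=("a", "b", "c"))
        assert kept == ["a", "c"]

    def test_panel_drop_set(self, small_cohort):
        """The redundancy rule removes the feather block (P7-P9, redundant
        with wing chord) and body mass (redundant with condition)."""
        _, _, traits, det = small_cohort
        candidates = features.build_feature_matrix(traits, det)
        kept = features.correlation_prune(candidates)
        dropped = set(candidates.columns) - set(kept)
        assert dropped == {"p7", "p8", "p9", "weight"}
        assert len(kept) == 14

    def test_independent_columns_kept(self, rng):
        table = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        assert features.correlation_prune(table) == ["a", "b"]

    def test_row_order_invariance(self, rng):
        x = rng.normal(size=300)
        table = pd.DataFrame({"a": x, "b": x + rng.normal(scale=0.1, size=300),
                              "c": rng.normal(size=300)})
        kept1 = features.correlation_prune(table)
        kept2 = features.correlation_prune(table.sample(frac=1, random_state=4))
        assert kept1 == kept2
        # idempotence
        assert features.correlation_prune(table[kept1]) == kept1


class TestMissingnessFilter:
    def _table(self, frac, n=100):
        col = np.ones(n)
        col[: int(frac * n)] = np.nan
        return col

    def test_rules(self):
        table = pd.DataFrame({
            "bad": self._table(0.30),
            "fall_timing": self._table(0.28),
            "boundary": self._table(0.25),
            "full": self._table(0.0),
        })
        kept = features.missingness_filter(table)
        assert "bad" not in kept            # > 25 % and not whitelisted
        assert "fall_timing" in kept        # whitelisted despite 28 %
        assert "boundary" in kept           # exactly 25 % -> kept (strict >)
        assert "full" in kept


class TestStandardize:
    def test_definition(self, rng):
        table = pd.DataFrame({"a": rng.normal(5, 3, 400), "b": rng.uniform(size=400)})
        z = features.Standardizer().fit_transform(table)
        assert np.allclose(z.mean(), 0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-9)

    def test_constant_column_error(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            features.Standardizer().fit(table)

    def test_no_leakage_contract(self, rng):
        train = pd.DataFrame({"a": rng.normal(0, 1, 200)})
        test = pd.DataFrame({"a": rng.normal(2, 1, 200)})  # shifted population
        std = features.Standardizer().fit(train)
        assert abs(std.transform(test)["a"].mean()) > 0.5


def _nan_euclidean_impute_bruteforce(X, k):
    """All-pairs oracle for the KNN imputer."""
    X = X.copy()
    n, d = X.shape
    out = X.copy()
    for i in range(n):
        for j in range(d):
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for other in range(n):
                if other == i or np.isnan(X[other, j]):
                    continue
                mask = ~(np.isnan(X[i]) | np.isnan(X[other]))
                if mask.sum() == 0:
                    continue
                dist = math.sqrt(d / mask.sum() * np.sum((X[i, mask] - X[other, mask]) ** 2))
                dists.append((dist, other))
            dists.sort()
            donors = [X[o, j] for _, o in dists[:k]]
            out[i, j] = np.mean(donors)
    return out


class TestKnnImpute:
    def test_hand_example(self):
        table = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [3.0, np.nan]], columns=["a", "b"])
        out, mask = features.knn_impute(table, k=2)
        assert out.loc[2, "b"] == pytest.approx(1.5)
        assert mask.loc[2, "b"] and not mask.loc[0, "a"]

    def test_identity_when_complete(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 3)))
        out, mask = features.knn_impute(table)
        pd.testing.assert_frame_equal(out, table.astype(float))
        assert not mask.to_numpy().any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        miss = rng.random(X.shape) < 0.2
        X[miss] = np.nan
        k = 3
        table = pd.DataFrame(X)
        out, _ = features.knn_impute(table, k=k)
        oracle = _nan_euclidean_impute_bruteforce(X, k)
        assert np.allclose(out.to_numpy(), oracle, atol=1e-10)

    def test_values_within_observed_range(self, rng):
        X = rng.normal(size=(50, 3))
        X[rng.random(X.shape) < 0.15] = np.nan
        table = pd.DataFrame(X)
        out, _ = features.knn_impute(table)
        for c in table.columns:
            obs = table[c].dropna()
            assert out[c].min() >= obs.min() - 1e-12
            assert out[c].max() <= obs.max() + 1e-12

    def test_all_missing_feature_error(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="no observed values"):
            features.knn_impute(table)


class TestStratifiedSplit:
    def test_class_counts(self):
        labels = np.array([0] * 415 + [1] * 185)  # 69.1 % / 30.9 % of 600
        train, test = features.stratified_split(labels, test_frac=0.2, seed=0)
        assert len(test) == 120
        assert np.sum(labels[test] == 0) == 83
        assert np.sum(labels[test] == 1) == 37

    def test_partition_properties(self, rng):
        labels = rng.integers(0, 2, 137)
        train, test = features.stratified_split(labels, seed=5)
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 137

    def test_deterministic(self, rng):
        labels = rng.integers(0, 2, 100)
        a = features.stratified_split(labels, seed=9)
        b = features.stratified_split(labels, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_small_class_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            features.stratified_split(np.array([0, 0, 0, 1]))


class TestPrepareFeatures:
    def test_panel_and_modes(self, small_cohort):
        _, _, traits, det = small_cohort
        candidates = features.build_feature_matrix(traits, det)
        y = traits["survived_true"].to_numpy()
        for mode in ("paper-literal", "strict"):
            prep = features.prepare_features(candidates, y, mode=mode, seed=1)
            assert len(prep.feature_names) == 14
            assert not prep.X_train.isna().any().any()
            assert not prep.X_test.isna().any().any()
            assert len(prep.y_test) == round(0.2 * len(y))
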