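"""Model benchmarking: splits, training, error normalization."""

import numpy as np
import pytest

from topolearn import (
    FeatureMatrix,
    LabeledDataset,
    RunRecord,
    make_split,
    normalize_errors,
    subsample_dataset,
    train_eval,
)
from topolearn.benchmark import ConfigurationError, InfeasibleSplitError


def linear_dataset(n=120, seed=0, noise=0.0, groups=None):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 4))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + noise * rng.normal(size=n)
    return LabeledDataset(FeatureMatrix(X), y, "lin", groups)


class TestMakeSplit:
    def test_random_split_deterministic(self):
        data = linear_dataset()
        a = make_split(data, "random", seed=5)
        b = make_split(data, "random", seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_random_split_partitions(self):
        data = linear_dataset()
        train, test = make_split(data, "random", test_fraction=0.25, seed=1)
        assert len(set(train) & set(test)) == 0
        assert len(train) + len(test) == data.n
        assert len(test) == 30

    def test_equal_groups_exact_count(self):
        groups = np.repeat(np.arange(10), 10)
        data = linear_dataset(n=100, groups=groups)
        train, test = make_split(data, "group", test_fraction=0.2, seed=3)
        assert len(np.unique(groups[test])) == 2
        assert len(test) == 20

    def test_group_split_never_leaks(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            groups = rng.integers(0, 15, 150)
            data = linear_dataset(n=150, seed=seed, groups=groups)
            train, test = make_split(data, "group", seed=seed)
            assert set(groups[train]).isdisjoint(set(groups[test]))

    def test_group_split_without_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            make_split(linear_dataset(), "group")

    def test_dominant_group_infeasible(self):
        groups = np.array([0] * 95 + list(range(1, 6)))
        data = linear_dataset(n=100, groups=groups)
        with pytest.raises(InfeasibleSplitError):
            make_split(data, "group", test_fraction=0.2, seed=0)


class TestTrainEval:
    def test_linear_labels_high_r2_both_families(self):
        data = linear_dataset(n=200, noise=0.0)
        split = make_split(data, "random", seed=0)
        small = {"forest": {"n_estimators": [200], "max_depth": [None]},
                 "neural": {"hidden_layer_sizes": [(64,)], "alpha": [1e-4]}}
        for family in ("forest", "neural"):
            rec = train_eval(data, split, family, small[family], seed=0)
            assert rec.errors["r2"] > 0.95, family

    def test_pure_noise_low_r2(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            data = LabeledDataset(
                FeatureMatrix(rng.random((150, 4))), rng.normal(size=150)
            )
            split = make_split(data, "random", seed=seed)
            rec = train_eval(
                data, split, "forest", {"n_estimators": [100], "max_depth": [None]},
                seed=seed,
            )
            assert rec.errors["r2"] <= 0.1

    def test_grid_of_size_one_is_forced_choice(self):
        data = linear_dataset()
        split = make_split(data, "random", seed=0)
        rec = train_eval(
            data, split, "forest", {"n_estimators": [37], "max_depth": [3]}, seed=0
        )
        assert rec.best_hyperparams == {"n_estimators": 37, "max_depth": 3}

    def test_constant_labels_r2_missing(self, caplog):
        data = LabeledDataset(
            FeatureMatrix(np.random.default_rng(0).random((60, 3))), np.ones(60)
        )
        split = make_split(data, "random", seed=0)
        with caplog.at_level("WARNING"):
            rec = train_eval(
                data, split, "forest", {"n_estimators": [10], "max_depth": [2]}, seed=0
            )
        assert np.isnan(rec.errors["r2"])


class TestNormalizeErrors:
    @staticmethod
    def records(values, dataset_id="d"):
        return [
            RunRecord(dataset_id, f"r{i}", 100, "random", "forest", {},
                      errors={"rmse": v, "mae": v})
            for i, v in enumerate(values)
        ]

    def test_direct_formula(self):
        recs = normalize_errors(self.records([2.0, 4.0, 6.0]))
        assert [r.errors_rel["rmse"] for r in recs] == [0.0, 0.5, 1.0]

    def test_boundaries_attained(self):
        recs = normalize_errors(self.records([5.0, 1.0, 3.0, 2.0]))
        rel = [r.errors_rel["rmse"] for r in recs]
        assert min(rel) == 0.0 and max(rel) == 1.0

    def test_affine_invariance(self):
        raw = [1.3, 2.9, 0.7, 2.1]
        a = normalize_errors(self.records(raw))
        b = normalize_errors(self.records([10.0 * v + 5.0 for v in raw]))
        for ra, rb in zip(a, b):
            assert ra.errors_rel["rmse"] == pytest.approx(rb.errors_rel["rmse"])

    def test_normalization_is_per_dataset(self):
        recs = self.records([1.0, 3.0], "d1") + self.records([10.0, 30.0], "d2")
        normalize_errors(recs)
        assert recs[0].errors_rel["rmse"] == 0.0 and recs[1].errors_rel["rmse"] == 1.0
        assert recs[2].errors_rel["rmse"] == 0.0 and recs[3].errors_rel["rmse"] == 1.0

    def test_all_tied_defined_as_zero(self, caplog):
        with caplog.at_level("WARNING"):
            recs = normalize_errors(self.records([2.0, 2.0, 2.0]))
        assert all(r.errors_rel["rmse"] == 0.0 for r in recs)


class TestSubsample:
    def test_full_size_identity_up_to_order(self):
        data = linear_dataset(n=50)
        sub = subsample_dataset(data, 50, seed=1)
        assert sorted(sub.features.row_ids) == sorted(data.features.row_ids)

    def test_reproducible(self):
        data = linear_dataset(n=100)
        a = subsample_dataset(data, 40, seed=7)
        b = subsample_dataset(data, 40, seed=7)
        assert a.features.row_ids == b.features.row_ids

    def test_two_seed_overlap_hypergeometric(self):
        data = linear_dataset(n=1000)
        a = set(subsample_dataset(data, 500, seed=1).features.row_ids)
        b = set(subsample_dataset(data, 500, seed=2).features.row_ids)
        assert abs(len(a & b) - 250) <= 50

    def test_groups_carried_along(self):
        groups = np.arange(100) % 7
        data = linear_dataset(n=100, groups=groups)
        sub = subsample_dataset(data, 30, seed=0)
        idx = [int(r[1:]) for r in sub.features.row_ids]
        np.testing.assert_array_equal(sub.group_ids, groups[idx])
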