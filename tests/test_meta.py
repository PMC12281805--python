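"""Meta-model assembly, fitting, leave-one-out CV and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topolearn import (
    MetaDataset,
    RunRecord,
    assemble_meta,
    correlation_screen,
    fit_meta,
    leave_one_out_cv,
)
from topolearn.meta import ConfigurationError, DegenerateTargetError

SMALL_GRID = {"n_estimators": [60], "max_depth": [None], "min_samples_leaf": [2]}


def make_records(n_datasets=5, n_reps=4, seed=0, target_fn=None, with_missing=False):
    """Synthetic records + descriptors with a planted descriptor→error link."""
    rng = np.random.default_rng(seed)
    records, descriptors = [], {}
    for d in range(n_datasets):
        for r in range(n_reps):
            for size in (100, 200):
                key = (f"D{d}", f"R{r}", size)
                desc = {
                    "betti_0": float(size - 1),
                    "lifetime_norm_0_avg": r / n_reps + 0.05 * rng.normal(),
                    "entropy_0": float(rng.normal()),
                }
                if with_missing and r == 0:
                    desc["entropy_1"] = float("nan")
                else:
                    desc["entropy_1"] = float(rng.normal())
                descriptors[key] = desc
                y = (
                    target_fn(desc, rng)
                    if target_fn
                    else np.clip(desc["lifetime_norm_0_avg"], 0, 1)
                )
                rec = RunRecord(
                    f"D{d}", f"R{r}", size, "random", "forest",
                    {"n_estimators": 100, "max_depth": None},
                    errors={"rmse": y, "mae": y},
                )
                rec.errors_rel = {"rmse": float(np.clip(y, 0, 1)), "mae": float(np.clip(y, 0, 1))}
                records.append(rec)
    return records, descriptors


class TestAssemble:
    def test_row_count_matches_keyed_records(self):
        records, desc = make_records()
        meta = assemble_meta(records, desc, "PH")
        assert meta.n == len(records)

    def test_missing_key_dropped_with_log(self, caplog):
        records, desc = make_records()
        del desc[("D0", "R0", 100)]
        with caplog.at_level("WARNING"):
            meta = assemble_meta(records, desc, "PH")
        assert meta.n == len(records) - 1
        assert any("dropped" in m for m in caplog.messages)

    def test_ph_feature_set_has_no_controls(self):
        records, desc = make_records()
        meta = assemble_meta(records, desc, "PH")
        assert not any("sample_size" in c or c.startswith("hp_") for c in meta.X.columns)
        meta_c = assemble_meta(records, desc, "C")
        assert "sample_size" in meta_c.X.columns
        assert any(c.startswith("hp_") for c in meta_c.X.columns)

    def test_missing_descriptor_becomes_nan_column(self):
        records, desc = make_records(with_missing=True)
        meta = assemble_meta(records, desc, "PH")
        assert meta.X["entropy_1"].isna().any()


class TestFitMeta:
    def test_planted_monotone_signal_recovered(self):
        records, desc = make_records(seed=1)
        meta = assemble_meta(records, desc, "PH")
        model = fit_meta(meta, grid=SMALL_GRID, seed=0)
        pred = model.predict(meta.X)
        assert stats.pearsonr(meta.y, pred)[0] > 0.95

    def test_predictions_clipped_to_unit_interval(self):
        records, desc = make_records(seed=2)
        meta = assemble_meta(records, desc, "PH")
        model = fit_meta(meta, grid=SMALL_GRID, seed=0)
        wild = meta.X.copy() * 1e6 - 500.0
        assert np.all(model.predict(wild) >= 0.0)
        assert np.all(model.predict(wild) <= 1.0)

    def test_degenerate_target_rejected(self):
        records, desc = make_records(target_fn=lambda d, rng: 0.5)
        meta = assemble_meta(records, desc, "PH")
        with pytest.raises(DegenerateTargetError):
            fit_meta(meta, grid=SMALL_GRID, seed=0)

    def test_too_few_rows_rejected(self):
        records, desc = make_records(n_datasets=1, n_reps=4)
        records = records[:6]
        meta = assemble_meta(records, desc, "PH")
        with pytest.raises(ConfigurationError):
            fit_meta(meta, grid=SMALL_GRID, seed=0)

    def test_importances_normalized(self):
        records, desc = make_records(seed=3)
        meta = assemble_meta(records, desc, "PH")
        model = fit_meta(meta, grid=SMALL_GRID, seed=0)
        imp = model.feature_importances
        assert all(v >= 0 for v in imp.values())
        assert sum(imp.values()) == pytest.approx(1.0)


class TestLeaveOneOutCV:
    def test_fold_structure(self):
        records, desc = make_records(n_datasets=5)
        meta = assemble_meta(records, desc, "PH")
        report = leave_one_out_cv(meta, "dataset_id", grid=SMALL_GRID, seed=0)
        assert report.scheme == "LODO"
        assert len(report.fold_groups) == 5
        assert len(report.fold_r) == 5

    def test_loro_groups_by_representation(self):
        records, desc = make_records(n_reps=4)
        meta = assemble_meta(records, desc, "PH")
        report = leave_one_out_cv(meta, "representation_id", grid=SMALL_GRID, seed=0)
        assert report.scheme == "LORO"
        assert len(report.fold_groups) == 4

    def test_no_leakage_between_folds(self, monkeypatch):
        # every fit must exclude the holdout group's rows
        records, desc = make_records(n_datasets=4)
        meta = assemble_meta(records, desc, "PH")
        seen = []
        import topolearn.meta as meta_mod

        original = meta_mod.fit_meta

        def spy(m, grid=None, seed=0, min_rows=30, _X=None, _y=None):
            seen.append(len(_y))
            return original(m, grid=grid, seed=seed, min_rows=min_rows, _X=_X, _y=_y)

        monkeypatch.setattr(meta_mod, "fit_meta", spy)
        meta_mod.leave_one_out_cv(meta, "dataset_id", grid=SMALL_GRID, seed=0)
        per_group = meta.n // 4
        assert seen == [meta.n - per_group] * 4

    def test_recovery_exceeds_permuted_null(self):
        records, desc = make_records(seed=4)
        meta = assemble_meta(records, desc, "PH")
        real = leave_one_out_cv(meta, "dataset_id", grid=SMALL_GRID, seed=0)
        rng = np.random.default_rng(0)
        perm = MetaDataset(
            X=meta.X, y=rng.permutation(meta.y), dataset_ids=meta.dataset_ids,
            representation_ids=meta.representation_ids, feature_set_tag="PH",
        )
        null = leave_one_out_cv(perm, "dataset_id", grid=SMALL_GRID, seed=0)
        assert real.r_a - null.r_a >= 0.4

    def test_too_few_groups_rejected(self):
        records, desc = make_records(n_datasets=2, n_reps=4)
        meta = assemble_meta(records, desc, "PH")
        with pytest.raises(ConfigurationError):
            leave_one_out_cv(meta, "dataset_id", grid=SMALL_GRID, seed=0)


class TestCorrelationScreen:
    @staticmethod
    def meta_from(X, y):
        n = len(y)
        return MetaDataset(
            X=pd.DataFrame(X), y=np.asarray(y, float),
            dataset_ids=np.array(["d"] * n), representation_ids=np.array(["r"] * n),
            feature_set_tag="PH",
        )

    def test_self_correlation(self):
        y = np.linspace(0, 1, 30)
        meta = self.meta_from({"same": y, "flip": -y}, y)
        tab = correlation_screen(meta).set_index("feature")
        assert tab.loc["same", "pearson_r"] == pytest.approx(1.0)
        assert tab.loc["same", "spearman_rho"] == pytest.approx(1.0)
        assert tab.loc["flip", "pearson_r"] == pytest.approx(-1.0)

    def test_constant_feature_missing(self):
        y = np.linspace(0, 1, 20)
        meta = self.meta_from({"const": np.ones(20)}, y)
        tab = correlation_screen(meta)
        assert np.isnan(tab.iloc[0]["pearson_r"])

    def test_independent_noise_small_correlation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.random(200)
            meta = self.meta_from({"noise": rng.normal(size=200)}, y)
            tab = correlation_screen(meta)
            if abs(tab.iloc[0]["pearson_r"]) < 0.2:
                hits += 1
        assert hits >= 19  # 95% over 20 seeds

    def test_pairwise_nan_dropping(self):
        y = np.linspace(0, 1, 40)
        x = y.copy()
        x[:5] = np.nan
        meta = self.meta_from({"partial": x}, y)
        tab = correlation_screen(meta)
        assert tab.iloc[0]["pearson_r"] == pytest.approx(1.0)
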