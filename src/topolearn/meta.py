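"""Meta-model: predicting normalized generalization error from topology.

Benchmark run records are joined with the topological descriptor
vectors of their (dataset, representation, sample size) configuration
to form a meta-dataset (X_t, y_t), y_t being the normalized test RMSE
in [0, 1].  A random forest regressor is grid-search tuned on X_t and
its predictions are clipped to [0, 1].

Two feature sets exist: ``PH`` (persistence descriptors and dimension
estimates only — the deployable predictor, usable before any model is
trained) and ``C`` (PH plus control variables: sample size, feature
dimensionality, metric, model family, split scheme, hyperparameters;
used to check that the topological signal is not a confound proxy).

Evaluation is leave-one-group-out over datasets (LODO-CV) or
representations (LORO-CV): r_cv is the mean ± std of per-fold Pearson
correlations between predicted and realized error, r_a the correlation
over all aggregated holdout predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .benchmark import RunRecord

logger = logging.getLogger(__name__)

META_GRID = {"n_estimators": [300], "max_depth": [None, 12], "min_samples_leaf": [1, 5]}

CONTROL_CATEGORICAL = ("metric_name", "model_family", "split_scheme")


class ConfigurationError(ValueError):
    pass


class DegenerateTargetError(ValueError):
    pass


@dataclass
class MetaDataset:
    """Meta-features X_t and target y_t (normalized RMSE) per run record."""

    X: pd.DataFrame
    y: np.ndarray
    dataset_ids: np.ndarray
    representation_ids: np.ndarray
    feature_set_tag: str

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class CVReport:
    scheme: str
    fold_groups: list
    fold_r: list
    r_cv_mean: float
    r_cv_std: float
    r_a: float
    feature_importances: dict = field(default_factory=dict)
    predictions: np.ndarray | None = None
    targets: np.ndarray | None = None


def descriptor_key(record: RunRecord) -> tuple:
    return (record.dataset_id, record.representation_id, record.sample_size)


def assemble_meta(
    records: list[RunRecord],
    descriptors: dict[tuple, dict[str, float]],
    feature_set_tag: str = "PH",
) -> MetaDataset:
    """Join run records with their descriptor vectors into (X_t, y_t).

    Records without a matching descriptor key are dropped with a logged
    identifier, never silently.  Categorical controls are one-hot
    encoded; hyperparameters become numeric columns (``None`` depth is
    encoded as -1).
    """
    if feature_set_tag not in ("PH", "C"):
        raise ConfigurationError("feature_set_tag must be 'PH' or 'C'")
    rows = []
    kept_records = []
    for rec in records:
        key = descriptor_key(rec)
        if key not in descriptors:
            logger.warning("assemble_meta: no descriptors for %s; row dropped", key)
            continue
        if "rmse" not in rec.errors_rel:
            logger.warning("assemble_meta: record %s lacks normalized rmse; dropped", key)
            continue
        row = dict(descriptors[key])
        if feature_set_tag == "C":
            row["sample_size"] = rec.sample_size
            row["model_family"] = rec.model_family
            row["split_scheme"] = rec.split_scheme
            for name, value in rec.best_hyperparams.items():
                row[f"hp_{name}"] = -1.0 if value is None else _numeric(value)
        rows.append(row)
        kept_records.append(rec)
    if not rows:
        raise ConfigurationError("no records could be joined with descriptors")
    X = pd.DataFrame(rows)
    if feature_set_tag == "C":
        cat_cols = [c for c in X.columns if X[c].dtype == object]
        X = pd.get_dummies(X, columns=cat_cols, dtype=float)
    X = X.reindex(sorted(X.columns), axis=1)
    y = np.array([rec.errors_rel["rmse"] for rec in kept_records])
    return MetaDataset(
        X=X,
        y=y,
        dataset_ids=np.array([rec.dataset_id for rec in kept_records]),
        representation_ids=np.array([rec.representation_id for rec in kept_records]),
        feature_set_tag=feature_set_tag,
    )


def _numeric(value) -> float:
    if isinstance(value, (bool, int, float)):
        return float(value)
    if isinstance(value, (tuple, list)):  # e.g. hidden layer sizes
        return float(np.sum(value))
    return float(hash(str(value)) % 10_000)


class _SentinelImputer:
    """Replace NaNs by a sentinel below the training minimum and add
    per-feature missing-indicator columns (fit on training rows only)."""

    def fit(self, X: pd.DataFrame) -> "_SentinelImputer":
        self.columns_ = list(X.columns)
        mins = X.min(axis=0, skipna=True)
        self.sentinel_ = (mins.fillna(0.0) - 1.0).to_dict()
        self.indicator_cols_ = [c for c in X.columns if X[c].isna().any()]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        X = X.reindex(self.columns_, axis=1)
        parts = [X.fillna(value=self.sentinel_)]
        for c in self.indicator_cols_:
            parts.append(X[c].isna().astype(float).rename(f"{c}__missing"))
        return pd.concat(parts, axis=1).to_numpy(dtype=float)


@dataclass
class MetaModel:
    """Fitted meta-predictor with its imputer and feature manifest."""

    estimator: RandomForestRegressor
    imputer: _SentinelImputer
    feature_names: list[str]
    best_params: dict
    version: str = "1"

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.estimator.predict(self.imputer.transform(X))
        return np.clip(raw, 0.0, 1.0)  # normalized error is bounded

    @property
    def feature_importances(self) -> dict[str, float]:
        cols = self.imputer.columns_ + [
            f"{c}__missing" for c in self.imputer.indicator_cols_
        ]
        imp = self.estimator.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return dict(zip(cols, imp.tolist()))


def fit_meta(
    meta: MetaDataset,
    grid: dict | None = None,
    seed: int = 0,
    min_rows: int = 30,
    _X: pd.DataFrame | None = None,
    _y: np.ndarray | None = None,
) -> MetaModel:
    """Fit the clipped random-forest meta-regressor with internal CV."""
    X = meta.X if _X is None else _X
    y = meta.y if _y is None else _y
    if len(y) < min_rows:
        raise ConfigurationError(f"need >= {min_rows} meta rows, got {len(y)}")
    if X.shape[1] == 0:
        raise ConfigurationError("empty feature set")
    if np.unique(y).size < 2:
        raise DegenerateTargetError("all meta targets identical")
    grid = META_GRID if grid is None else grid
    imputer = _SentinelImputer().fit(X)
    Xn = imputer.transform(X)
    search = GridSearchCV(
        RandomForestRegressor(random_state=seed, n_jobs=1),
        grid,
        scoring="neg_root_mean_squared_error",
        cv=KFold(5, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(Xn, y)
    cols = imputer.columns_ + [f"{c}__missing" for c in imputer.indicator_cols_]
    return MetaModel(
        estimator=search.best_estimator_,
        imputer=imputer,
        feature_names=cols,
        best_params=dict(search.best_params_),
    )


def leave_one_out_cv(
    meta: MetaDataset,
    group_by: str = "dataset_id",
    grid: dict | None = None,
    seed: int = 0,
) -> CVReport:
    """LODO-CV (group_by="dataset_id") or LORO-CV ("representation_id").

    Each fold fits on every row outside one group and predicts that
    group's rows; folds with fewer than 3 rows or constant targets are
    recorded as missing and excluded from the r_cv mean.
    """
    if group_by == "dataset_id":
        groups, scheme = meta.dataset_ids, "LODO"
    elif group_by == "representation_id":
        groups, scheme = meta.representation_ids, "LORO"
    else:
        raise ConfigurationError("group_by must be dataset_id or representation_id")
    unique = sorted(np.unique(groups).tolist())
    if len(unique) < 3:
        raise ConfigurationError("need >= 3 distinct groups for leave-one-out CV")
    fold_r: list[float] = []
    preds = np.full(meta.n, np.nan)
    importances: list[dict[str, float]] = []
    for g in unique:
        hold = groups == g
        model = fit_meta(
            meta,
            grid=grid,
            seed=seed,
            min_rows=1,
            _X=meta.X.loc[~hold],
            _y=meta.y[~hold],
        )
        p = model.predict(meta.X.loc[hold])
        preds[hold] = p
        importances.append(model.feature_importances)
        if hold.sum() < 3 or np.unique(meta.y[hold]).size < 2 or np.unique(p).size < 2:
            logger.warning("fold %s: too few rows or constant values; r missing", g)
            fold_r.append(float("nan"))
            continue
        fold_r.append(float(stats.pearsonr(meta.y[hold], p)[0]))
    valid = np.array([r for r in fold_r if not np.isnan(r)])
    r_a = float(stats.pearsonr(meta.y, preds)[0]) if np.unique(preds).size > 1 else float("nan")
    agg_imp: dict[str, float] = {}
    for imp in importances:
        for k, v in imp.items():
            agg_imp[k] = agg_imp.get(k, 0.0) + v / len(importances)
    total = sum(agg_imp.values())
    if total > 0:
        agg_imp = {k: v / total for k, v in agg_imp.items()}
    return CVReport(
        scheme=scheme,
        fold_groups=unique,
        fold_r=fold_r,
        r_cv_mean=float(np.mean(valid)) if valid.size else float("nan"),
        r_cv_std=float(np.std(valid)) if valid.size else float("nan"),
        r_a=r_a,
        feature_importances=agg_imp,
        predictions=preds,
        targets=meta.y.copy(),
    )


def permutation_null(
    meta: MetaDataset,
    group_by: str = "dataset_id",
    n_shuffles: int = 5,
    grid: dict | None = None,
    seed: int = 0,
) -> list[float]:
    """Aggregated-prediction correlations r_a under permuted targets.

    The normalized error y_t is a within-dataset min–max quantity, so
    the exchangeable unit under the null hypothesis ("descriptors carry
    no information about which configuration of a dataset errs more")
    is the row *within its dataset*: targets are shuffled within each
    dataset, which preserves every fold's target distribution.  A global
    shuffle would instead perturb fold means and inject the well-known
    leave-group-out regression-to-the-mean artifact (expected r of about
    −1/sqrt(rows per fold) even for a perfect implementation).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        y = meta.y.copy()
        for g in np.unique(meta.dataset_ids):
            idx = np.nonzero(meta.dataset_ids == g)[0]
            y[idx] = y[rng.permutation(idx)]
        shuffled = MetaDataset(
            X=meta.X,
            y=y,
            dataset_ids=meta.dataset_ids,
            representation_ids=meta.representation_ids,
            feature_set_tag=meta.feature_set_tag,
        )
        out.append(leave_one_out_cv(shuffled, group_by, grid=grid, seed=seed).r_a)
    return out


def correlation_screen(meta: MetaDataset, min_rows: int = 10) -> pd.DataFrame:
    """Per-feature Pearson and Spearman correlation with the target.

    Missing values are pairwise-dropped; constant features are recorded
    with NaN correlations.  P-values are two-tailed.
    """
    if meta.n < min_rows:
        raise ConfigurationError(f"need >= {min_rows} rows for correlations")
    rows = []
    for col in meta.X.columns:
        x = meta.X[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        xv, yv = x[ok], meta.y[ok]
        if xv.size < 3 or np.unique(xv).size < 2 or np.unique(yv).size < 2:
            rows.append((col, np.nan, np.nan, np.nan, np.nan))
            continue
        r, pr = stats.pearsonr(xv, yv)
        rho, ps = stats.spearmanr(xv, yv)
        rows.append((col, float(r), float(pr), float(rho), float(ps)))
    return pd.DataFrame(
        rows, columns=["feature", "pearson_r", "pearson_p", "spearman_rho", "spearman_p"]
    )
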