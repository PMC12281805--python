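"""Regression benchmarking across representations and dataset sizes.

Each configuration (dataset, representation, sample size, split scheme,
model family) is trained with 5-fold grid-search cross-validation on the
training side of a single seeded holdout split, then evaluated on the
test side.  Raw errors (RMSE, MAE, R²) are normalized per dataset to
[0, 1] so representation quality is comparable across datasets of
different difficulty: E_rel = (E − E_min) / (E_max − E_min) over all
runs of the same dataset.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor

from .geometry import ValidationError
from .modelability import LabeledDataset

logger = logging.getLogger(__name__)

#: desk-scale hyperparameter grids for the two model families
DEFAULT_GRIDS = {
    "forest": {"n_estimators": [100, 500], "max_depth": [None, 10]},
    "neural": {
        "hidden_layer_sizes": [(64,), (128, 64)],
        "alpha": [1e-4, 1e-3],
    },
}


class ConfigurationError(ValueError):
    pass


class InfeasibleSplitError(ValueError):
    pass


@dataclass
class RunRecord:
    """Result of one training configuration."""

    dataset_id: str
    representation_id: str
    sample_size: int
    split_scheme: str
    model_family: str
    best_hyperparams: dict
    errors: dict = field(default_factory=dict)  # rmse, mae, r2 (raw)
    errors_rel: dict = field(default_factory=dict)  # rmse, mae in [0, 1]
    seed: int = 0


def subsample_dataset(data: LabeledDataset, size: int, seed: int) -> LabeledDataset:
    """Seeded uniform subsample without replacement, groups carried along."""
    if size > data.n:
        raise ValidationError(f"subsample size {size} exceeds n={data.n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.n, size=size, replace=False)
    return data.subset(np.sort(idx))


def make_split(
    data: LabeledDataset,
    scheme: str = "random",
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test index sets; group scheme keeps each group on one side."""
    if scheme not in ("random", "group"):
        raise ConfigurationError(f"unknown split scheme {scheme!r}")
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.n
    target = int(round(n * test_fraction))
    if scheme == "random":
        perm = rng.permutation(n)
        return np.sort(perm[target:]), np.sort(perm[:target])
    if data.group_ids is None:
        raise ConfigurationError("group split requested but group_ids are absent")
    groups = np.asarray(data.group_ids)
    unique = np.unique(groups)
    sizes = {g: int(np.sum(groups == g)) for g in unique}
    if max(sizes.values()) > n - target:
        raise InfeasibleSplitError(
            "largest group exceeds the training side; group split infeasible"
        )
    order = rng.permutation(unique)
    test_groups = []
    count = 0
    for g in order:
        if count >= target:
            break
        if count + sizes[g] <= n - 1:  # never consume every molecule
            test_groups.append(g)
            count += sizes[g]
    mask = np.isin(groups, test_groups)
    return np.nonzero(~mask)[0], np.nonzero(mask)[0]


def _build_estimator(model_family: str, seed: int):
    if model_family == "forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if model_family == "neural":
        return MLPRegressor(
            random_state=seed, early_stopping=True, max_iter=500
        )
    raise ConfigurationError(f"unknown model family {model_family!r}")


def train_eval(
    data: LabeledDataset,
    split: tuple[np.ndarray, np.ndarray],
    model_family: str = "forest",
    grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    split_scheme: str = "random",
    standardize_labels: bool = False,
) -> RunRecord:
    """Grid-search CV on the training side, evaluation on the test side.

    ``standardize_labels`` z-scores the labels on training statistics
    and inverts the transform before scoring (off by default; it does
    not change the relative ordering of configurations).
    """
    grid = DEFAULT_GRIDS[model_family] if grid is None else grid
    if not grid:
        raise ConfigurationError("hyperparameter grid must be non-empty")
    train_idx, test_idx = split
    Xtr, ytr = data.features.values[train_idx], data.labels[train_idx]
    Xte, yte = data.features.values[test_idx], data.labels[test_idx]
    y_loc, y_scale = 0.0, 1.0
    if standardize_labels:
        y_loc = float(np.mean(ytr))
        y_scale = float(np.std(ytr)) or 1.0
        ytr = (ytr - y_loc) / y_scale
    est = _build_estimator(model_family, seed)
    search = GridSearchCV(
        est,
        grid,
        scoring="neg_root_mean_squared_error",
        cv=KFold(cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    t0 = time.perf_counter()
    search.fit(Xtr, ytr)
    pred = search.predict(Xte) * y_scale + y_loc
    logger.info(
        "train_eval %s/%s n=%d %s/%s: best=%s (%.2fs)",
        data.dataset_id, data.features.representation_id, data.n,
        split_scheme, model_family, search.best_params_, time.perf_counter() - t0,
    )
    errors = {
        "rmse": float(np.sqrt(mean_squared_error(yte, pred))),
        "mae": float(mean_absolute_error(yte, pred)),
    }
    if np.ptp(ytr) == 0.0 or np.ptp(yte) == 0.0:
        logger.warning("train_eval: constant labels; r2 undefined, recorded missing")
        errors["r2"] = float("nan")
    else:
        errors["r2"] = float(r2_score(yte, pred))
    return RunRecord(
        dataset_id=data.dataset_id,
        representation_id=data.features.representation_id,
        sample_size=data.n,
        split_scheme=split_scheme,
        model_family=model_family,
        best_hyperparams=dict(search.best_params_),
        errors=errors,
        seed=seed,
    )


def normalize_errors(records: list[RunRecord], metrics: tuple[str, ...] = ("rmse", "mae")) -> list[RunRecord]:
    """Min–max normalize each error metric within each dataset batch.

    Mutates and returns ``records``; within a dataset the smallest raw
    error maps to 0 and the largest to 1 (all tied → 0 with a warning).
    Min–max scaling is invariant to affine transforms of the raw errors.
    """
    by_dataset: dict[str, list[RunRecord]] = {}
    for rec in records:
        by_dataset.setdefault(rec.dataset_id, []).append(rec)
    for dataset_id, batch in by_dataset.items():
        if len(batch) < 2:
            raise ValidationError(
                f"dataset {dataset_id!r} has fewer than 2 records to normalize"
            )
        for metric in metrics:
            vals = np.array([rec.errors[metric] for rec in batch])
            lo, hi = float(np.min(vals)), float(np.max(vals))
            if hi - lo == 0.0:
                logger.warning(
                    "normalize_errors: all %s tied in dataset %s; E_rel = 0",
                    metric,
                    dataset_id,
                )
                for rec in batch:
                    rec.errors_rel[metric] = 0.0
            else:
                for rec in batch:
                    rec.errors_rel[metric] = (rec.errors[metric] - lo) / (hi - lo)
    return records
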