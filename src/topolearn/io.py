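"""CSV/JSON input and output.

CSV is the interchange format for matrices, diagrams, descriptors and
run records; JSON for reports and resolved configurations.  Feature and
label CSVs carry molecule identifiers in the first column and are
cross-checked on load.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    FeatureMatrix,
    PersistenceDiagram,
    PersistenceInterval,
    ValidationError,
)
from .modelability import LabeledDataset

logger = logging.getLogger(__name__)


class IdMismatchError(ValueError):
    """Feature and label identifiers disagree; message lists the diff."""


@dataclasses.dataclass
class RunConfig:
    """Serializable description of a pipeline run.

    A persisted config re-runs to identical outputs for every
    deterministic stage; all stochastic stages derive from ``seed``.
    """

    features_csv: str | None = None
    labels_csv: str | None = None
    groups_csv: str | None = None
    metric: str | None = None
    descriptor_scope: str = "all"  # "all" or "train"
    n_datasets: int = 4
    n_representations: int = 4
    sizes: list[int] = dataclasses.field(default_factory=lambda: [150, 300])
    split_schemes: list[str] = dataclasses.field(default_factory=lambda: ["random"])
    seed: int = 0
    outdir: str = "topolearn_out"

    def to_json(self, path: str | Path) -> None:
        write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_tabular(path: str | Path, kind: str = "features"):
    """Read a CSV with header and ids in the first column.

    ``kind="features"`` returns a :class:`FeatureMatrix`; ``labels`` and
    ``groups`` return a pandas Series indexed by molecule id.
    """
    if kind not in ("features", "labels", "groups"):
        raise ValidationError(f"unknown tabular kind {kind!r}")
    df = pd.read_csv(path, header=0, index_col=0)
    df.index = df.index.astype(str)
    if kind == "features":
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
        kind_guess = (
            "binary_fingerprint" if np.isin(values, (0.0, 1.0)).all() else "embedding"
        )
        return FeatureMatrix(
            values,
            row_ids=list(df.index),
            representation_id=Path(path).stem,
            representation_kind=kind_guess,
        )
    series = df.iloc[:, 0]
    if kind == "labels":
        try:
            series = series.astype(float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric label in {path}: {exc}") from exc
    return series


def load_labeled_dataset(
    features_path: str | Path,
    labels_path: str | Path,
    groups_path: str | Path | None = None,
    dataset_id: str | None = None,
) -> LabeledDataset:
    """Join feature/label (and optional group) CSVs, checking id sets."""
    X = read_tabular(features_path, "features")
    y = read_tabular(labels_path, "labels")
    fids, lids = set(X.row_ids), set(y.index)
    if fids != lids:
        missing_in_labels = sorted(fids - lids)[:20]
        missing_in_features = sorted(lids - fids)[:20]
        raise IdMismatchError(
            f"id mismatch: {len(fids - lids)} ids missing from labels "
            f"(e.g. {missing_in_labels}), {len(lids - fids)} missing from "
            f"features (e.g. {missing_in_features})"
        )
    y = y.loc[X.row_ids]  # align to feature row order
    groups = None
    if groups_path is not None:
        g = read_tabular(groups_path, "groups")
        if set(g.index) != fids:
            raise IdMismatchError("group ids do not match feature ids")
        groups = g.loc[X.row_ids].to_numpy()
    return LabeledDataset(
        features=X,
        labels=y.to_numpy(),
        dataset_id=dataset_id or Path(features_path).stem,
        group_ids=groups,
    )


def write_diagram(diag: PersistenceDiagram, path: str | Path) -> None:
    """Persist a finalized diagram as hom_dim,birth,death rows."""
    df = pd.DataFrame(
        [(iv.hom_dim, iv.birth, iv.death) for iv in diag.intervals],
        columns=["hom_dim", "birth", "death"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_diagram(
    path: str | Path, n_points: int, metric_name: str = "euclidean"
) -> PersistenceDiagram:
    df = pd.read_csv(path)
    intervals = [
        PersistenceInterval(int(r.hom_dim), float(r.birth), float(r.death))
        for r in df.itertuples()
    ]
    return PersistenceDiagram(intervals, n_points=n_points, metric_name=metric_name)


def write_descriptors(rows: list[dict], path: str | Path) -> None:
    """One CSV row per (dataset, representation, configuration)."""
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_descriptors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_records(records: list, path: str | Path) -> None:
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        row["best_hyperparams"] = json.dumps(row["best_hyperparams"])
        for metric, v in row.pop("errors").items():
            row[f"error_{metric}"] = v
        for metric, v in row.pop("errors_rel").items():
            row[f"error_rel_{metric}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
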