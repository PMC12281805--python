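"""Seeded generators of synthetic point clouds, landscapes and benchmarks.

These stand in for molecular datasets so every stage of the pipeline is
testable with known ground truth:

* point clouds of known topology and intrinsic dimension (circle,
  sphere, hypercube, Gaussian blobs, line) plus fingerprint-like
  Bernoulli bit matrices;
* property landscapes over a cloud: a smooth radial sinusoid with a
  known Lipschitz constant, optionally corrupted by "activity cliffs"
  (a seeded fraction of points gets a large constant label offset,
  breaking nearest-neighbor continuity the way cliff compound pairs do);
* a full planted meta-benchmark: a grid of datasets × representations
  whose representation quality degrades monotonically through additive
  feature noise, so realized model error and topology both respond to a
  known knob.

Everything is fully determined by (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .benchmark import (
    RunRecord,
    make_split,
    normalize_errors,
    subsample_dataset,
    train_eval,
)
from .descriptors import compute_descriptors
from .dimension import estimate_dimensions
from .geometry import FeatureMatrix, ValidationError, pairwise_distances, vr_persistence
from .modelability import LabeledDataset

SHAPES = ("circle", "sphere", "hypercube", "gaussian_blobs", "line", "fingerprint")

#: angular frequency of the smooth radial label function; its Lipschitz
#: constant over the feature metric equals this value.
LANDSCAPE_OMEGA = 2.0

#: cliff offset factor: planted cliffs shift the label by this multiple
#: of the smooth label range, guaranteeing a discontinuity far above any
#: smooth neighbor gap.
CLIFF_OFFSET_FACTOR = 3.0


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic point cloud."""

    shape: str = "hypercube"
    n: int = 200
    dim: int = 2  # manifold/ambient parameter (hypercube d, blobs ambient)
    n_blobs: int = 3
    noise_sd: float = 0.0
    bit_density: float = 0.3
    n_bits: int = 256
    cliff_fraction: float = 0.0
    label_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValidationError(f"unknown shape {self.shape!r}; known: {SHAPES}")
        if not 0.0 <= self.cliff_fraction <= 1.0:
            raise ValidationError("cliff_fraction must lie in [0, 1]")
        if self.n < 10:
            raise ValidationError("n must be >= 10")


def make_point_cloud(spec: SyntheticSpec) -> FeatureMatrix:
    """Sample the named manifold plus isotropic noise (seeded)."""
    rng = np.random.default_rng(spec.seed)
    kind = "embedding"
    if spec.shape == "circle":
        theta = rng.uniform(0, 2 * np.pi, spec.n)
        pts = np.c_[np.cos(theta), np.sin(theta)]
    elif spec.shape == "sphere":
        v = rng.normal(size=(spec.n, 3))
        pts = v / np.linalg.norm(v, axis=1, keepdims=True)
    elif spec.shape == "hypercube":
        pts = rng.uniform(0, 1, (spec.n, spec.dim))
    elif spec.shape == "gaussian_blobs":
        centers = rng.uniform(-4, 4, (spec.n_blobs, spec.dim))
        assign = rng.integers(spec.n_blobs, size=spec.n)
        pts = centers[assign] + rng.normal(0, 0.5, (spec.n, spec.dim))
    elif spec.shape == "line":
        direction = rng.normal(size=spec.dim)
        direction /= np.linalg.norm(direction)
        t = rng.uniform(0, 1, spec.n)
        pts = np.outer(t, direction)
    else:  # fingerprint
        bits = rng.random((spec.n, spec.n_bits)) < spec.bit_density
        return FeatureMatrix(
            bits.astype(float),
            representation_id=f"synthetic-{spec.shape}",
            representation_kind="binary_fingerprint",
        )
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0, spec.noise_sd, pts.shape)
    return FeatureMatrix(
        pts, representation_id=f"synthetic-{spec.shape}", representation_kind=kind
    )


def smooth_labels(cloud: FeatureMatrix) -> np.ndarray:
    """Smooth radial label function sin(ω · ||x − x̄||), Lipschitz with
    constant ω in the euclidean feature metric."""
    center = cloud.values.mean(axis=0)
    r = np.linalg.norm(cloud.values - center, axis=1)
    return np.sin(LANDSCAPE_OMEGA * r)


def make_landscape(
    cloud: FeatureMatrix,
    cliff_fraction: float = 0.0,
    label_noise_sd: float = 0.0,
    seed: int = 0,
    dataset_id: str = "synthetic",
    n_groups: int | None = None,
) -> LabeledDataset:
    """Property landscape over a cloud with planted activity cliffs.

    A seeded fraction of points has its smooth label shifted by a
    constant offset of three times the smooth label range; a cliffed
    point next to a smooth one therefore violates any Lipschitz bound
    the smooth field obeys.  Group identifiers for scaffold-style splits
    come from seeded spatial k-means clustering.
    """
    if not 0.0 <= cliff_fraction <= 1.0:
        raise ValidationError("cliff_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = smooth_labels(cloud)
    y = base.copy()
    n = cloud.n
    n_cliffs = int(round(cliff_fraction * n))
    cliff_idx = rng.choice(n, size=n_cliffs, replace=False)
    offset = CLIFF_OFFSET_FACTOR * (base.max() - base.min() + 1e-12)
    y[cliff_idx] += offset
    if label_noise_sd > 0:
        y = y + rng.normal(0, label_noise_sd, n)
    k = n_groups if n_groups is not None else max(2, n // 30)
    km = KMeans(n_clusters=k, random_state=int(rng.integers(2**31 - 1)), n_init=3)
    groups = km.fit_predict(cloud.values)
    return LabeledDataset(
        features=cloud, labels=y, dataset_id=dataset_id, group_ids=groups
    )


@dataclass
class MetaBenchmark:
    """Planted benchmark: run records plus descriptor lookup.

    ``planted_distortion`` records each representation's noise level —
    the roughness knob: distorting the feature space scrambles
    neighborhoods, which manifests as activity cliffs *in that
    representation's metric* and as higher realized model error.
    """

    records: list[RunRecord]
    descriptors: dict[tuple, dict[str, float]]
    planted_distortion: dict[str, float] = field(default_factory=dict)
    planted_label_noise: dict[str, float] = field(default_factory=dict)


def _representation_transform(
    base: np.ndarray, rep_index: int, distortion: float, rng: np.random.Generator
) -> np.ndarray:
    """Embed base coordinates linearly and corrupt them with noise.

    Higher ``distortion`` drowns the label-relevant geometry in isotropic
    noise, degrading both the achievable model error and the topological
    structure — the planted monotone association the meta-model learns.
    """
    d_in = base.shape[1]
    d_out = d_in + 2 + rep_index  # representations differ in dimensionality
    Q = rng.normal(size=(d_in, d_out)) / np.sqrt(d_in)
    emb = base @ Q
    return emb + distortion * rng.normal(size=emb.shape)


def make_meta_benchmark(
    n_datasets: int = 4,
    n_representations: int = 4,
    seed: int = 0,
    sizes: tuple[int, ...] = (150, 300),
    split_schemes: tuple[str, ...] = ("random",),
    grid: dict | None = None,
    compute_dims: bool = True,
    descriptor_scope: str = "all",
) -> MetaBenchmark:
    """Generate the planted end-to-end benchmark at reduced scale.

    ``n_datasets`` smooth base landscapes (varying blob structure and
    label noise) are each featurized by ``n_representations``
    representations of increasing noise distortion — the planted
    roughness axis — then subsampled to each size, benchmarked with the
    forest family and normalized per dataset.  Descriptors (persistence
    summary statistics and dimension estimates) are computed per
    configuration.
    """
    if n_datasets < 4 or n_representations < 4:
        raise ValidationError("need >= 4 datasets and >= 4 representations")
    if descriptor_scope not in ("all", "train"):
        raise ValidationError("descriptor_scope must be 'all' or 'train'")
    grid = {"n_estimators": [100], "max_depth": [None, 10]} if grid is None else grid
    rng = np.random.default_rng(seed)
    pool_n = max(sizes) * 2
    noise_levels = np.linspace(0.02, 0.1, n_datasets)
    distortions = np.linspace(0.0, 1.8, n_representations)

    records: list[RunRecord] = []
    descriptors: dict[tuple, dict[str, float]] = {}
    planted_distortion = {}
    planted_label_noise = {}
    for di in range(n_datasets):
        ds_id = f"D{di}"
        planted_label_noise[ds_id] = float(noise_levels[di])
        base_spec = SyntheticSpec(
            shape="gaussian_blobs",
            n=pool_n,
            dim=3,
            n_blobs=3 + di % 3,
            seed=int(rng.integers(2**31 - 1)),
        )
        cloud = make_point_cloud(base_spec)
        landscape = make_landscape(
            cloud,
            cliff_fraction=0.0,
            label_noise_sd=float(noise_levels[di]),
            seed=int(rng.integers(2**31 - 1)),
            dataset_id=ds_id,
        )
        for ri in range(n_representations):
            rep_id = f"R{ri}"
            planted_distortion[rep_id] = float(distortions[ri])
            rep_rng = np.random.default_rng([seed % (2**31 - 1), di, ri])
            rep_values = _representation_transform(
                cloud.values, ri, float(distortions[ri]), rep_rng
            )
            rep_data = LabeledDataset(
                features=FeatureMatrix(
                    rep_values,
                    row_ids=list(cloud.row_ids),
                    representation_id=rep_id,
                    representation_kind="embedding",
                ),
                labels=landscape.labels,
                dataset_id=ds_id,
                group_ids=landscape.group_ids,
            )
            for size in sizes:
                sub_seed = int(rep_rng.integers(2**31 - 1))
                sub = subsample_dataset(rep_data, size, seed=sub_seed)
                key = (ds_id, rep_id, size)
                splits = {
                    scheme: make_split(sub, scheme=scheme, seed=sub_seed)
                    for scheme in split_schemes
                }
                if descriptor_scope == "train":
                    first = split_schemes[0]
                    desc_features = sub.subset(splits[first][0]).features
                else:
                    desc_features = sub.features
                D = pairwise_distances(desc_features, "euclidean")
                diag = vr_persistence(D, max_hom_dim=1)
                desc = compute_descriptors(diag)
                if compute_dims:
                    n_desc = desc_features.n
                    sizes_grid = sorted(set(np.linspace(50, n_desc, 6).astype(int).tolist()))
                    est = estimate_dimensions(
                        desc_features,
                        "euclidean",
                        seed=sub_seed,
                        sizes=sizes_grid,
                        k_neighbors=min(50, n_desc - 1),
                    )
                    desc.update(est.as_dict())
                descriptors[key] = desc
                for scheme, split in splits.items():
                    rec = train_eval(
                        sub,
                        split,
                        model_family="forest",
                        grid=grid,
                        seed=sub_seed,
                        split_scheme=scheme,
                    )
                    records.append(rec)
    normalize_errors(records)
    return MetaBenchmark(
        records=records,
        descriptors=descriptors,
        planted_distortion=planted_distortion,
        planted_label_noise=planted_label_noise,
    )
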