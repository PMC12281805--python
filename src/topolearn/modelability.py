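"""Baseline QSAR landscape roughness and modelability indices.

Activity cliffs — structurally similar molecules with very different
properties — make a dataset hard to model.  Four classical indices
quantify this:

* **SALI**: per pair, |ΔA| / (1 − sim).  Pairs with sim = 1 (duplicates
  under the metric) are masked and counted instead of producing NaNs.
* **SARI**: ½(score_cont + (1 − score_disc)) where the continuity score
  is the potency-weighted mean similarity of dissimilar pairs and the
  discontinuity score the mean potency difference of similar pairs
  (similarity threshold 0.65); both raw scores are min–max normalized
  within the batch of datasets being compared.  Higher = smoother.
* **RMODI**: fraction of molecules whose nearest neighbor's label
  differs by less than a tolerance times the label range.
* **ROGI / ROGI-XD**: integrated loss of label dispersion 2(σ0 − σt)
  as the dataset is coarse-grained by cutting a complete-linkage
  dendrogram, either by normalized distance threshold t (classic) or by
  the cluster-count reparameterization t = 1 − (k − 1)/(n − 1) (xd).
  Rougher landscapes lose dispersion sooner, giving larger values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .geometry import DistanceMatrix, FeatureMatrix, ValidationError, pairwise_distances

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Feature matrix plus per-molecule property labels.

    ``group_ids`` (e.g. precomputed scaffold identifiers) enable group
    splits; they are optional.
    """

    features: FeatureMatrix
    labels: np.ndarray
    dataset_id: str = "unnamed"
    group_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.ndim != 1 or self.labels.size != self.features.n:
            raise ValidationError("labels must be a vector of length n")
        if not np.all(np.isfinite(self.labels)):
            raise ValidationError("labels must be finite")
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if self.group_ids.shape != (self.features.n,):
                raise ValidationError("group_ids must have length n")

    @property
    def n(self) -> int:
        return self.features.n

    def subset(self, idx: np.ndarray, dataset_id: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            features=FeatureMatrix(
                self.features.values[idx],
                row_ids=[self.features.row_ids[i] for i in idx],
                representation_id=self.features.representation_id,
                representation_kind=self.features.representation_kind,
            ),
            labels=self.labels[idx],
            dataset_id=dataset_id or self.dataset_id,
            group_ids=None if self.group_ids is None else self.group_ids[idx],
        )


@dataclass
class ModelabilityScores:
    sali_matrix: np.ndarray | None = None
    sali_mean: float = float("nan")
    sali_max: float = float("nan")
    masked_pairs: int = 0
    sari: float = float("nan")
    rmodi: float = float("nan")
    rogi: float = float("nan")
    rogi_xd: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


def default_similarity(data: LabeledDataset) -> np.ndarray:
    """Similarity matrix: Tanimoto for binary features, 1/(1+euclidean) else."""
    if data.features.representation_kind == "binary_fingerprint":
        D = pairwise_distances(data.features, "jaccard")
        return 1.0 - D.values
    D = pairwise_distances(data.features, "euclidean")
    return 1.0 / (1.0 + D.values)


def _check_similarity(sim: np.ndarray, n: int) -> None:
    if sim.shape != (n, n):
        raise ValidationError("similarity matrix shape mismatch")
    if not np.allclose(sim, sim.T, atol=1e-10):
        raise ValidationError("similarity matrix must be symmetric")
    if np.any(sim < -1e-12) or np.any(sim > 1.0 + 1e-12):
        raise ValidationError("similarities must lie in [0, 1]")


def sali(data: LabeledDataset, similarity: np.ndarray | None = None) -> ModelabilityScores:
    """Structure–activity landscape index, pairwise and summarized.

    Off-diagonal pairs with similarity 1 are masked (NaN in the matrix)
    and counted in ``masked_pairs``; summary statistics run over the
    remaining pairs.
    """
    sim = default_similarity(data) if similarity is None else np.asarray(similarity, float)
    _check_similarity(sim, data.n)
    A = data.labels
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.abs(A[:, None] - A[None, :]) / (1.0 - sim)
    np.fill_diagonal(mat, np.nan)
    iu, ju = np.triu_indices(data.n, k=1)
    dup = np.isclose(sim[iu, ju], 1.0)
    mat[iu[dup], ju[dup]] = np.nan
    mat[ju[dup], iu[dup]] = np.nan
    masked = int(np.count_nonzero(dup))
    if masked:
        logger.warning("sali: %d duplicate pairs (sim = 1) masked", masked)
    vals = mat[iu, ju]
    vals = vals[~np.isnan(vals)]
    out = ModelabilityScores(sali_matrix=mat, masked_pairs=masked)
    if vals.size == 0:
        logger.warning("sali: all pairs masked; summaries undefined")
        out.diagnostics["all_masked"] = True
        return out
    out.sali_mean = float(np.mean(vals))
    out.sali_max = float(np.max(vals))
    return out


def _sari_raw(
    data: LabeledDataset, similarity: np.ndarray | None, sim_threshold: float
) -> tuple[float, float]:
    """Raw (continuity, discontinuity) scores of one dataset."""
    if data.n < 3:
        raise InsufficientDataError("sari requires n >= 3")
    sim = default_similarity(data) if similarity is None else np.asarray(similarity, float)
    _check_similarity(sim, data.n)
    iu, ju = np.triu_indices(data.n, k=1)
    s = sim[iu, ju]
    dA = np.abs(data.labels[iu] - data.labels[ju])
    # continuity: potency-weighted mean similarity over dissimilar pairs
    lo = s < sim_threshold
    if np.any(lo) and np.sum(dA[lo]) > 0:
        cont = float(np.sum(dA[lo] * s[lo]) / np.sum(dA[lo]))
    else:
        cont = 0.0
    # discontinuity: mean potency gap over similar pairs
    hi = s >= sim_threshold
    if np.any(hi):
        disc = float(np.mean(dA[hi]))
    else:
        logger.warning("sari: no pair above similarity threshold; discontinuity = 0")
        disc = 0.0
    return cont, disc


def sari_batch(
    datasets: list[LabeledDataset],
    similarities: list[np.ndarray] | None = None,
    sim_threshold: float = 0.65,
) -> np.ndarray:
    """SARI for a batch of datasets, min–max normalized within the batch.

    For a batch of one the min–max is degenerate; the natural-range
    fallback is used instead (continuity is already a weighted mean of
    similarities in [0, 1]; discontinuity is divided by the label range).
    """
    raws = [
        _sari_raw(d, None if similarities is None else similarities[k], sim_threshold)
        for k, d in enumerate(datasets)
    ]
    cont = np.array([r[0] for r in raws])
    disc = np.array([r[1] for r in raws])

    def _minmax(v: np.ndarray) -> np.ndarray:
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi - lo == 0.0:
            return np.full(v.shape, 0.5)
        return (v - lo) / (hi - lo)

    if len(datasets) >= 2:
        cont_n, disc_n = _minmax(cont), _minmax(disc)
    else:
        rng_y = np.ptp(datasets[0].labels)
        cont_n = cont
        disc_n = disc / rng_y if rng_y > 0 else np.zeros_like(disc)
        disc_n = np.clip(disc_n, 0.0, 1.0)
    return 0.5 * (cont_n + (1.0 - disc_n))


def sari(
    data: LabeledDataset,
    similarity: np.ndarray | None = None,
    sim_threshold: float = 0.65,
) -> float:
    """SARI of a single dataset (batch of one; see :func:`sari_batch`)."""
    return float(
        sari_batch([data], None if similarity is None else [similarity], sim_threshold)[0]
    )


def rmodi(
    data: LabeledDataset,
    distance: DistanceMatrix | None = None,
    label_tolerance: float = 0.1,
) -> float:
    """Regression modelability index: fraction of cliff-free neighborhoods.

    For each molecule i with first nearest neighbor j, the rivality-style
    score RI_i = |y_i − y_j| / range(y) − tolerance is negative when the
    neighborhood is smooth; RMODI is the fraction of negative scores.
    """
    if data.n < 2:
        raise InsufficientDataError("rmodi requires n >= 2")
    if not 0.0 < label_tolerance < 1.0:
        raise ValidationError("label_tolerance must lie in (0, 1)")
    D = pairwise_distances(data.features) if distance is None else distance
    y = data.labels
    rng_y = float(np.ptp(y))
    if rng_y == 0.0:
        logger.warning("rmodi: constant labels; defined as 1.0")
        return 1.0
    dm = D.values.copy()
    np.fill_diagonal(dm, np.inf)
    nn = np.argmin(dm, axis=1)  # ties -> smallest index (argmin contract)
    ri = np.abs(y - y[nn]) / rng_y - label_tolerance
    return float(np.mean(ri < 0))


def _complete_linkage_sigma(
    dm: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """σ of the coarse-grained label vector after each dendrogram merge.

    Returns (merge heights ascending, σ after each merge).  Coarse
    graining replaces each member's label by its cluster mean, so σ is
    the square root of the between-cluster variance, updated
    incrementally along the merge sequence.
    """
    n = y.size
    Z = linkage(squareform(dm, checks=False), method="complete")
    heights = Z[:, 2]
    # cluster bookkeeping: scipy assigns new cluster id n + step
    sums = np.concatenate([y, np.zeros(n - 1)])
    counts = np.concatenate([np.ones(n), np.zeros(n - 1)])
    ybar = float(np.mean(y))
    # between-cluster sum of squares term Σ n_c * mean_c^2
    sq = float(np.sum(y**2))
    sigmas = np.empty(n - 1)
    for step in range(n - 1):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        sq -= sums[a] ** 2 / counts[a] + sums[b] ** 2 / counts[b]
        sums[n + step] = sums[a] + sums[b]
        counts[n + step] = counts[a] + counts[b]
        sq += sums[n + step] ** 2 / counts[n + step]
        var = max(sq / n - ybar**2, 0.0)
        sigmas[step] = np.sqrt(var)
    return heights, sigmas


def rogi(
    data: LabeledDataset,
    distance: DistanceMatrix | None = None,
    n_thresholds: int = 51,
    variant: str = "classic",
) -> float:
    """Roughness index: integrated dispersion loss under coarse-graining.

    ``variant="classic"`` cuts the complete-linkage dendrogram of
    max-normalized distances at an even grid of thresholds t in [0, 1];
    ``variant="xd"`` walks the merge sequence and places the k-cluster
    partition at t = 1 − (k − 1)/(n − 1), removing the direct dependence
    of the threshold scale on representation dimensionality.
    """
    if variant not in ("classic", "xd"):
        raise ValidationError("variant must be 'classic' or 'xd'")
    if data.n < 3:
        raise InsufficientDataError("rogi requires n >= 3")
    D = pairwise_distances(data.features) if distance is None else distance
    y = data.labels
    sigma0 = float(np.std(y))
    if sigma0 == 0.0:
        return 0.0
    dm = D.values
    if variant == "classic":
        dmax = float(np.max(dm))
        if dmax > 0:
            dm = dm / dmax
    heights, sigmas = _complete_linkage_sigma(dm, y)
    if variant == "classic":
        t_grid = np.linspace(0.0, 1.0, n_thresholds)
        # σ(t) is a step function dropping at each merge height <= t
        idx = np.searchsorted(heights, t_grid, side="right")
        sigma_t = np.where(idx == 0, sigma0, sigmas[np.maximum(idx - 1, 0)])
        return float(np.trapezoid(2.0 * (sigma0 - sigma_t), t_grid))
    # xd: k = n clusters at t = 0 down to 1 cluster at t = 1
    n = data.n
    k_values = np.arange(n, 0, -1)  # after 0 .. n-1 merges
    t_vals = 1.0 - (k_values - 1) / (n - 1)
    sigma_k = np.concatenate([[sigma0], sigmas])
    return float(np.trapezoid(2.0 * (sigma0 - sigma_k), t_vals))


def modelability_report(
    data: LabeledDataset,
    similarity: np.ndarray | None = None,
    distance: DistanceMatrix | None = None,
) -> ModelabilityScores:
    """All indices of one dataset in a single pass."""
    D = pairwise_distances(data.features) if distance is None else distance
    out = sali(data, similarity)
    try:
        out.sari = sari(data, similarity)
    except InsufficientDataError as exc:
        logger.warning("sari unavailable: %s", exc)
    out.rmodi = rmodi(data, D)
    try:
        out.rogi = rogi(data, D, variant="classic")
        out.rogi_xd = rogi(data, D, variant="xd")
    except InsufficientDataError as exc:
        logger.warning("rogi unavailable: %s", exc)
    return out
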