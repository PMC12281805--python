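"""Intrinsic-dimension estimators of feature-space point clouds.

Three estimators are provided:

* **PH-dimension** — a fractal-type dimension from the growth of total
  persistence with sample size.  For subsamples of size s the α-weighted
  sum of interval lengths E^α = Σ (d − b)^α scales as s^m with
  m → (dim − α)/dim, so the slope m of log E^α against log s gives the
  estimate α / (1 − m).  Defaults: α = 1, subsample sizes 100, 150, …,
  2000 capped at n, one draw per size.
* **TwoNN** — per point, the ratio μ = r2/r1 of the distances to its two
  nearest neighbors is Pareto(dim)-distributed on a locally uniform
  manifold; the slope through the origin of −log(1 − F(μ)) against
  log μ is the dimension.  The top ``discard_fraction`` of ratios is
  dropped to tame heavy-tail noise.
* **local PCA** — per point, eigenvalues of the covariance of its k
  nearest neighbors are counted above ``eigen_threshold`` times the
  leading eigenvalue; the estimate is the mean count over points.

Degenerate inputs (all points identical, zero covariance, slope ≥ 1)
yield NaN with a diagnostic rather than an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .geometry import (
    FeatureMatrix,
    ValidationError,
    mst_deaths,
    pairwise_distances,
    vr_persistence,
)

logger = logging.getLogger(__name__)

_SKLEARN_METRIC = {
    "euclidean": "euclidean",
    "manhattan": "manhattan",
    "cosine": "cosine",
    "jaccard": "jaccard",
}


class InsufficientDataError(ValueError):
    """Too few points or subsample sizes for the requested estimate."""


class DuplicatePointsError(ValueError):
    """Duplicate rows break estimators that need r1 > 0."""


@dataclass
class DimensionEstimates:
    """Container for the estimates and their regression diagnostics."""

    dim_ph_0: float = float("nan")
    dim_ph_1: float = float("nan")
    dim_twonn: float = float("nan")
    dim_pca: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "dim_ph_0": self.dim_ph_0,
            "dim_ph_1": self.dim_ph_1,
            "dim_twonn": self.dim_twonn,
            "dim_pca": self.dim_pca,
        }


def default_sizes(n: int) -> list[int]:
    return [s for s in range(100, 2001, 50) if s <= n]


def ph_dimension(
    X: FeatureMatrix,
    metric_name: str | None = None,
    hom_dim: int = 0,
    sizes: list[int] | None = None,
    alpha: float = 1.0,
    seed: int = 0,
    repeats: int = 1,
) -> DimensionEstimates:
    """PH-dimension estimate α / (1 − m) from the subsampling slope m.

    For each size s, ``repeats`` seeded subsamples are drawn without
    replacement, persistence is computed for ``hom_dim``, and the mean
    E^α = Σ lifetime^α enters an ordinary least-squares fit of
    log E^α on log s.
    """
    sizes = default_sizes(X.n) if sizes is None else [s for s in sizes if s <= X.n]
    if len(sizes) < 4:
        raise InsufficientDataError(
            f"need at least 4 usable subsample sizes <= n={X.n}, got {len(sizes)}"
        )
    rng = np.random.default_rng(seed)
    e_alpha = []
    for s in sizes:
        vals = []
        for _ in range(repeats):
            idx = rng.choice(X.n, size=s, replace=False)
            sub = FeatureMatrix(
                X.values[idx],
                row_ids=[X.row_ids[i] for i in idx],
                representation_id=X.representation_id,
                representation_kind=X.representation_kind,
            )
            D = pairwise_distances(sub, metric_name)
            if hom_dim == 0:
                lifetimes = mst_deaths(D)
            else:
                diag = vr_persistence(D, max_hom_dim=1)
                lifetimes = diag.lifetimes(1)
            vals.append(float(np.sum(lifetimes**alpha)))
        e_alpha.append(float(np.mean(vals)))
    e_alpha_arr = np.array(e_alpha)
    est = DimensionEstimates()
    diag_info: dict = {
        "alpha": alpha,
        "sizes": list(sizes),
        "e_alpha": e_alpha,
        "hom_dim": hom_dim,
    }
    if np.any(e_alpha_arr <= 0):
        logger.warning("ph_dimension: zero total persistence (degenerate geometry)")
        diag_info["degenerate"] = True
        est.diagnostics = diag_info
        return est
    m, _ = np.polyfit(np.log(sizes), np.log(e_alpha_arr), 1)
    diag_info["slope"] = float(m)
    if m >= 1.0:
        logger.warning("ph_dimension: slope m=%.3f >= 1, estimate undefined", m)
        diag_info["degenerate"] = True
        est.diagnostics = diag_info
        return est
    value = alpha / (1.0 - m)
    if hom_dim == 0:
        est.dim_ph_0 = value
    else:
        est.dim_ph_1 = value
    est.diagnostics = diag_info
    return est


def twonn_dimension(
    X: FeatureMatrix,
    metric_name: str | None = None,
    discard_fraction: float = 0.1,
) -> float:
    """TwoNN global intrinsic dimension."""
    if X.n < 20:
        raise InsufficientDataError("twonn_dimension requires n >= 20")
    if metric_name is None:
        metric_name = X.default_metric()
    nn = NearestNeighbors(n_neighbors=3, metric=_SKLEARN_METRIC[metric_name])
    nn.fit(X.values)
    dist, _ = nn.kneighbors(X.values)
    r1, r2 = dist[:, 1], dist[:, 2]
    dup = np.nonzero(r1 <= 0)[0]
    if dup.size:
        ids = [X.row_ids[i] for i in dup[:10]]
        raise DuplicatePointsError(
            f"{dup.size} points have a duplicate (r1 = 0), e.g. rows {ids}"
        )
    mu = np.sort(r2 / r1)
    n = mu.size
    F = np.arange(1, n + 1) / n
    keep = int(np.floor(n * (1.0 - discard_fraction)))
    mu, F = mu[:keep], F[:keep]
    x = np.log(mu)
    y = -np.log(1.0 - F)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        logger.warning("twonn_dimension: all distance ratios equal 1")
        return float("nan")
    return float(np.dot(x, y) / denom)  # least squares through the origin


def lpca_dimension(
    X: FeatureMatrix,
    k_neighbors: int = 100,
    eigen_threshold: float = 0.05,
) -> float:
    """Local-PCA intrinsic dimension, averaged over neighborhoods.

    For every point, the covariance eigenvalues λ1 >= … >= λd of its k
    nearest neighbors are computed and eigenvalues above
    ``eigen_threshold * λ1`` counted; the mean count over all points is
    returned.
    """
    if not 0.0 < eigen_threshold < 1.0:
        raise ValidationError("eigen_threshold must lie in (0, 1)")
    k = min(k_neighbors, X.n - 1)
    if k < 2:
        raise InsufficientDataError("lpca_dimension requires n >= 3")
    nn = NearestNeighbors(n_neighbors=k + 1)
    nn.fit(X.values)
    _, idx = nn.kneighbors(X.values)
    counts = np.empty(X.n)
    for i in range(X.n):
        nbrs = X.values[idx[i, 1:]]  # exclude the point itself
        cov = np.cov(nbrs, rowvar=False)
        eig = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
        if eig[0] <= 0:
            counts[i] = np.nan
            continue
        counts[i] = np.count_nonzero(eig > eigen_threshold * eig[0])
    if np.all(np.isnan(counts)):
        logger.warning("lpca_dimension: zero covariance everywhere (constant matrix)")
        return float("nan")
    return float(np.nanmean(counts))


def estimate_dimensions(
    X: FeatureMatrix,
    metric_name: str | None = None,
    seed: int = 0,
    sizes: list[int] | None = None,
    alpha: float = 1.0,
    include_ph_1: bool = False,
    k_neighbors: int = 100,
) -> DimensionEstimates:
    """All dimension estimates of one feature matrix, NaN where degenerate.

    PH-dimension errors from too-small n are recorded as NaN here (the
    caller asked for "whatever is estimable"); the individual estimators
    raise instead.
    """
    est = DimensionEstimates()
    try:
        frag = ph_dimension(X, metric_name, hom_dim=0, sizes=sizes, alpha=alpha, seed=seed)
        est.dim_ph_0 = frag.dim_ph_0
        est.diagnostics["ph_0"] = frag.diagnostics
    except InsufficientDataError as exc:
        logger.warning("dim_ph_0 unavailable: %s", exc)
    if include_ph_1:
        try:
            frag = ph_dimension(
                X, metric_name, hom_dim=1, sizes=sizes, alpha=alpha, seed=seed
            )
            est.dim_ph_1 = frag.dim_ph_1
            est.diagnostics["ph_1"] = frag.diagnostics
        except InsufficientDataError as exc:
            logger.warning("dim_ph_1 unavailable: %s", exc)
    try:
        est.dim_twonn = twonn_dimension(X, metric_name)
    except (InsufficientDataError, DuplicatePointsError) as exc:
        logger.warning("dim_twonn unavailable: %s", exc)
    try:
        est.dim_pca = lpca_dimension(X, k_neighbors=k_neighbors)
    except (InsufficientDataError, ValidationError) as exc:
        logger.warning("dim_pca unavailable: %s", exc)
    return est
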