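"""Distance matrices and Vietoris–Rips persistent homology.

The central objects are point clouds of molecules in a representation's
feature space.  Their shape is summarized by the Vietoris–Rips filtration:
the nested family of clique complexes obtained by connecting every pair of
points within a growing distance scale.  Persistent homology tracks
connected components (homological dimension 0) and independent cycles
(dimension 1) along the filtration; each feature is an interval
``(birth, death)``.

Dimension-0 intervals are computed from the minimum spanning tree of the
complete distance graph: every MST edge weight is the death of one
component merge, so the full filtration yields exactly ``n - 1`` finite
bars, all born at 0.  Dimension-1 intervals come from a mod-2 column
reduction of the triangle boundary matrix of the clique 2-skeleton,
restricted to edges below the enclosing radius (the smallest scale at
which some vertex dominates the graph, beyond which the complex is a cone
and all cycles are dead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from ._reduction import h1_persistence_pairs

logger = logging.getLogger(__name__)

SUPPORTED_METRICS = ("euclidean", "manhattan", "cosine", "jaccard")

#: default metric per representation kind: Jaccard for bit vectors
#: (1 - Tanimoto similarity), Euclidean otherwise.
DEFAULT_METRICS = {
    "binary_fingerprint": "jaccard",
    "descriptor": "euclidean",
    "embedding": "euclidean",
}


class MetricMismatchError(ValueError):
    """Requested metric is incompatible with the representation values."""


class ValidationError(ValueError):
    """Input object violates a structural invariant."""


@dataclass
class FeatureMatrix:
    """An ``n x d`` molecular feature matrix.

    Parameters
    ----------
    values
        Real matrix, rows are molecules.  Binary entries are allowed and
        required for ``representation_kind="binary_fingerprint"``.
    row_ids
        Molecule identifiers, one per row.
    representation_id
        Name of the representation that produced the features.
    representation_kind
        One of ``binary_fingerprint``, ``descriptor``, ``embedding``.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    representation_id: str = "unnamed"
    representation_kind: str = "embedding"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValidationError("feature matrix must be 2-D with n >= 1, d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite entries")
        if not self.row_ids:
            self.row_ids = [f"m{i}" for i in range(self.values.shape[0])]
        if len(self.row_ids) != self.values.shape[0]:
            raise ValidationError("row_ids length does not match matrix")
        if self.representation_kind not in DEFAULT_METRICS:
            raise ValidationError(
                f"unknown representation_kind {self.representation_kind!r}"
            )
        if self.representation_kind == "binary_fingerprint" and not self.is_binary:
            raise ValidationError("binary_fingerprint matrix has entries outside {0, 1}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def default_metric(self) -> str:
        return DEFAULT_METRICS[self.representation_kind]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a named metric."""

    values: np.ndarray
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10, rtol=0.0):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("distance matrix must have zero diagonal")
        if np.any(v < 0.0):
            raise ValidationError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PersistenceInterval:
    """One topological feature: (homological dimension, birth, death)."""

    hom_dim: int
    birth: float
    death: float

    def __post_init__(self) -> None:
        if self.death <= self.birth:
            raise ValidationError("persistence interval requires death > birth")

    @property
    def lifetime(self) -> float:
        return self.death - self.birth

    @property
    def midlife(self) -> float:
        return 0.5 * (self.birth + self.death)


@dataclass
class PersistenceDiagram:
    """Finalized diagram: finite intervals only, grouped by dimension."""

    intervals: list[PersistenceInterval]
    n_points: int
    metric_name: str = "euclidean"
    threshold: float | None = None

    def by_dim(self, hom_dim: int) -> list[PersistenceInterval]:
        return [iv for iv in self.intervals if iv.hom_dim == hom_dim]

    def lifetimes(self, hom_dim: int) -> np.ndarray:
        return np.array([iv.lifetime for iv in self.by_dim(hom_dim)], dtype=float)

    def midlives(self, hom_dim: int) -> np.ndarray:
        return np.array([iv.midlife for iv in self.by_dim(hom_dim)], dtype=float)

    def betti(self, hom_dim: int) -> int:
        return len(self.by_dim(hom_dim))


def pairwise_distances(X: FeatureMatrix, metric_name: str | None = None) -> DistanceMatrix:
    """Compute the pairwise distance matrix of a feature matrix.

    ``metric_name=None`` picks the representation-kind default (Jaccard
    for binary fingerprints, Euclidean otherwise).  Jaccard distance on
    bit vectors is ``1 - |a & b| / |a | b|``; a pair of all-zero rows is
    defined to have distance 0 (identical empty substructure sets) and
    logged as a warning.
    """
    if metric_name is None:
        metric_name = X.default_metric()
    if metric_name not in SUPPORTED_METRICS:
        raise ValidationError(
            f"unsupported metric {metric_name!r}; supported: {SUPPORTED_METRICS}"
        )
    V = X.values
    if metric_name == "jaccard":
        if not X.is_binary:
            raise MetricMismatchError(
                "jaccard distance requires a binary feature matrix "
                f"(representation {X.representation_id!r} is not binary)"
            )
        B = V.astype(bool)
        zero_rows = ~B.any(axis=1)
        if np.count_nonzero(zero_rows) >= 2:
            logger.warning(
                "jaccard: %d all-zero rows; their pairwise distance is defined as 0",
                int(np.count_nonzero(zero_rows)),
            )
        condensed = pdist(B, metric="jaccard")  # scipy: empty/empty -> 0
        D = squareform(condensed)
    elif metric_name == "manhattan":
        D = squareform(pdist(V, metric="cityblock"))
    else:
        D = squareform(pdist(V, metric=metric_name))
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, D.T)  # enforce exact symmetry against fp jitter
    return DistanceMatrix(values=D, metric_name=metric_name)


def mst_deaths(D: DistanceMatrix) -> np.ndarray:
    """Edge weights of a minimum spanning forest, ascending.

    These are exactly the deaths of the dimension-0 persistence intervals
    of the Vietoris–Rips filtration (each MST edge merges two components).
    """
    if D.n < 2:
        raise ValidationError("mst_deaths requires n >= 2")
    # scipy reads a zero entry as "no edge"; shift all weights by a
    # constant (which leaves the MST edge set unchanged) so duplicate
    # points keep their zero-weight merge edges.
    shifted = D.values + 1.0
    np.fill_diagonal(shifted, 0.0)
    mst = minimum_spanning_tree(shifted)
    weights = np.maximum(np.asarray(mst.data) - 1.0, 0.0)
    return np.sort(weights)


def _edge_list(D: np.ndarray, max_weight: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edges (i < j) with weight <= max_weight, in filtration order.

    Order is (weight, i, j) lexicographic — the deterministic tie-break.
    """
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = D[iu, ju]
    keep = w <= max_weight
    iu, ju, w = iu[keep], ju[keep], w[keep]
    # triu enumeration is (i, j)-lexicographic; stable sort by weight
    # leaves ties in that deterministic order
    order = np.argsort(w, kind="stable")
    return iu[order], ju[order], w[order]


def _enclosing_radius(D: np.ndarray) -> float:
    """Smallest r such that some vertex is within r of all others.

    At this scale the clique complex is a cone, hence contractible: every
    dimension >= 1 class dies at or before it, so the filtration can be
    truncated there without changing the finite part of the diagram.
    """
    return float(np.min(np.max(D, axis=1)))


def _h1_intervals(D: np.ndarray, max_scale: float) -> list[tuple[float, float]]:
    """Dimension-1 intervals via mod-2 reduction of the clique 2-skeleton."""
    n = D.shape[0]
    if n < 3:
        return []
    ei, ej, ew = _edge_list(D, max_scale)
    n_edges = ei.size
    if n_edges < 3:
        return []
    edge_rank = np.full((n, n), -1, dtype=np.int64)
    edge_rank[ei, ej] = np.arange(n_edges)
    edge_rank[ej, ei] = np.arange(n_edges)
    adj = np.zeros((n, n), dtype=bool)
    adj[ei, ej] = True
    adj[ej, ei] = True
    births, deaths = h1_persistence_pairs(adj, edge_rank, ew, ei, ej)
    keep = deaths > births
    return list(zip(births[keep].tolist(), deaths[keep].tolist()))


def vr_persistence(
    D: DistanceMatrix, max_hom_dim: int = 1, threshold: float | None = None
) -> PersistenceDiagram:
    """Vietoris–Rips persistent homology up to homological dimension 1.

    Returns only finite intervals: the single infinite dimension-0 bar of
    the surviving component (and any bar still open at ``threshold``) is
    removed, and zero-length intervals are discarded.

    Dimension 0 uses the minimum-spanning-tree shortcut; dimension 1
    reduces the mod-2 boundary matrix of the clique complex restricted to
    simplices of dimension <= 2.
    """
    if max_hom_dim not in (0, 1):
        raise ValidationError("max_hom_dim must be 0 or 1")
    if D.n < 2:
        logger.warning("vr_persistence on n < 2 points: empty diagram")
        return PersistenceDiagram([], n_points=D.n, metric_name=D.metric_name,
                                  threshold=threshold)
    intervals: list[PersistenceInterval] = []
    deaths = mst_deaths(D)
    if threshold is not None:
        deaths = deaths[deaths <= threshold]
    for d in deaths:
        if d > 0.0:
            intervals.append(PersistenceInterval(0, 0.0, float(d)))
    if max_hom_dim >= 1 and D.n >= 3:
        max_scale = _enclosing_radius(D.values)
        if threshold is not None:
            max_scale = min(max_scale, threshold)
        for birth, death in _h1_intervals(D.values, max_scale):
            if death > birth:
                intervals.append(PersistenceInterval(1, float(birth), float(death)))
    return PersistenceDiagram(
        intervals=intervals, n_points=D.n, metric_name=D.metric_name, threshold=threshold
    )
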