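"""Brute-force Vietoris–Rips persistence by full boundary-matrix reduction.

A deliberately simple, slow implementation used as an independent check of
the production path in :mod:`topolearn.geometry`: it enumerates every
simplex of dimension <= 2, sorts the whole filtration at once, and reduces
the global mod-2 boundary matrix column by column with Python sets.  No
minimum-spanning-tree shortcut, no enclosing-radius truncation, no
compiled code.  Intended for point clouds of a few dozen points.
"""

from __future__ import annotations

from itertools import combinations

from .geometry import (
    DistanceMatrix,
    PersistenceDiagram,
    PersistenceInterval,
)


def vr_persistence_bruteforce(
    D: DistanceMatrix, max_hom_dim: int = 1, threshold: float | None = None
) -> PersistenceDiagram:
    """Full-reduction Vietoris–Rips persistence for dimensions 0 and 1.

    Matches :func:`topolearn.geometry.vr_persistence` on the finite part
    of the diagram (infinite and zero-length intervals removed).
    """
    n = D.n
    dm = D.values
    limit = float("inf") if threshold is None else threshold

    # (filtration value, dim, vertex tuple) for every simplex of dim <= 2
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for v in range(n):
        simplices.append((0.0, 0, (v,)))
    for i, j in combinations(range(n), 2):
        w = dm[i, j]
        if w <= limit:
            simplices.append((float(w), 1, (i, j)))
    if max_hom_dim >= 1:
        for i, j, k in combinations(range(n), 3):
            w = max(dm[i, j], dm[i, k], dm[j, k])
            if w <= limit:
                simplices.append((float(w), 2, (i, j, k)))
    # faces before cofaces: value, then dimension, then lexicographic
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of = {s[2]: idx for idx, s in enumerate(simplices)}

    columns: list[set[int]] = []
    for _, dim, verts in simplices:
        if dim == 0:
            columns.append(set())
        else:
            faces = combinations(verts, dim)
            columns.append({index_of[f] for f in faces})

    pivot_of: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []  # (birth simplex idx, death simplex idx)
    for idx, col in enumerate(columns):
        while col:
            piv = max(col)
            owner = pivot_of.get(piv)
            if owner is None:
                pivot_of[piv] = idx
                pairs.append((piv, idx))
                break
            col ^= columns[owner]

    intervals: list[PersistenceInterval] = []
    for birth_idx, death_idx in pairs:
        bval, bdim, _ = simplices[birth_idx]
        dval, _, _ = simplices[death_idx]
        if bdim > max_hom_dim or dval <= bval:
            continue
        intervals.append(PersistenceInterval(bdim, bval, dval))
    return PersistenceDiagram(
        intervals=intervals, n_points=n, metric_name=D.metric_name, threshold=threshold
    )
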