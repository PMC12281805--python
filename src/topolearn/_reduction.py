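"""Dimension-1 Vietoris–Rips pairs via coboundary reduction with clearing.

Direct column reduction of the triangle boundary matrix is correct but
slow on clique filtrations: nearly every triangle column is positive and
must be ground down to zero.  The production path therefore reduces the
anti-transpose (persistent-cohomology order): columns are edges processed
in reverse filtration order, rows their cofacet triangles, pivot = the
earliest cofacet.  Two standard facts make this fast:

* the resulting (edge, triangle) pairs are identical to those of the
  direct reduction (anti-transpose duality);
* columns of edges that are negative in dimension 0 (the Kruskal/MST
  edges under the same tie-break order) reduce to zero and can be
  skipped outright (clearing).

The direct homology kernel is kept as :func:`reduce_triangle_boundary`
for cross-checking.  All kernels are numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _count_triangles(adj):  # pragma: no cover - jitted
    n = adj.shape[0]
    total = 0
    for a in range(n - 2):
        for b in range(a + 1, n - 1):
            if not adj[a, b]:
                continue
            for c in range(b + 1, n):
                if adj[a, c] and adj[b, c]:
                    total += 1
    return total


@njit(cache=True)
def _fill_triangles(adj, edge_rank, edge_w, out_rows, out_vals):  # pragma: no cover
    n = adj.shape[0]
    t = 0
    for a in range(n - 2):
        for b in range(a + 1, n - 1):
            if not adj[a, b]:
                continue
            for c in range(b + 1, n):
                if adj[a, c] and adj[b, c]:
                    e0 = edge_rank[a, b]
                    e1 = edge_rank[a, c]
                    e2 = edge_rank[b, c]
                    # sort the three edge ranks ascending
                    if e0 > e1:
                        e0, e1 = e1, e0
                    if e1 > e2:
                        e1, e2 = e2, e1
                    if e0 > e1:
                        e0, e1 = e1, e0
                    out_rows[t, 0] = e0
                    out_rows[t, 1] = e1
                    out_rows[t, 2] = e2
                    # filtration value of a clique = its longest edge
                    out_vals[t] = edge_w[e2]
                    t += 1
    return t


@njit(cache=True)
def _group_cofacets(tri_rows, n_edges):  # pragma: no cover - jitted
    """Counting-sort triangles into per-edge cofacet lists.

    Triangles are visited in rank order, so each edge's list comes out
    ascending by triangle rank.
    """
    m = tri_rows.shape[0]
    counts = np.zeros(n_edges + 1, np.int64)
    for t in range(m):
        for q in range(3):
            counts[tri_rows[t, q] + 1] += 1
    for e in range(n_edges):
        counts[e + 1] += counts[e]
    cof = np.empty(3 * m, np.int64)
    fill = counts[:-1].copy()
    for t in range(m):
        for q in range(3):
            e = tri_rows[t, q]
            cof[fill[e]] = t
            fill[e] += 1
    return cof, counts


@njit(cache=True)
def _kruskal_negative_edges(ei, ej, n_vertices):  # pragma: no cover - jitted
    """Mark edges that merge components when added in filtration order."""
    parent = np.arange(n_vertices)
    negative = np.zeros(ei.shape[0], np.bool_)
    merges = 0
    for e in range(ei.shape[0]):
        ra = ei[e]
        while parent[ra] != ra:
            parent[ra] = parent[parent[ra]]
            ra = parent[ra]
        rb = ej[e]
        while parent[rb] != rb:
            parent[rb] = parent[parent[rb]]
            rb = parent[rb]
        if ra != rb:
            parent[ra] = rb
            negative[e] = True
            merges += 1
            if merges == n_vertices - 1:
                break
    return negative


@njit(cache=True)
def _coreduce(cof, cof_off, m_triangles, skip_col):  # pragma: no cover - jitted
    """Reduce edge coboundary columns, edges in reverse filtration order.

    ``cof[cof_off[e]:cof_off[e+1]]`` lists the cofacet triangle ranks of
    edge ``e`` ascending; the pivot of a column is its smallest triangle
    rank (= largest row of the anti-transpose).  Columns flagged in
    ``skip_col`` are cleared.  Returns paired (edge, triangle-rank)
    arrays.
    """
    n_edges = cof_off.shape[0] - 1
    pivot_owner = np.full(m_triangles, -1, np.int64)
    cap = 4 * (cof.shape[0] + 16)
    buf = np.empty(cap, np.int64)
    starts = np.empty(n_edges, np.int64)
    lens = np.empty(n_edges, np.int64)
    n_stored = 0
    buf_used = 0
    pair_edge = np.empty(n_edges, np.int64)
    pair_tri = np.empty(n_edges, np.int64)
    n_pairs = 0
    cur = np.empty(m_triangles, np.int64)
    tmp = np.empty(m_triangles, np.int64)
    for e in range(n_edges - 1, -1, -1):
        if skip_col[e]:
            continue
        lc = cof_off[e + 1] - cof_off[e]
        for q in range(lc):
            cur[q] = cof[cof_off[e] + q]
        while lc > 0:
            piv = cur[0]  # smallest triangle rank = anti-transpose pivot
            owner = pivot_owner[piv]
            if owner == -1:
                if buf_used + lc > cap:
                    newcap = cap
                    while newcap < buf_used + lc:
                        newcap *= 2
                    nb = np.empty(newcap, np.int64)
                    nb[:buf_used] = buf[:buf_used]
                    buf = nb
                    cap = newcap
                starts[n_stored] = buf_used
                lens[n_stored] = lc
                for q in range(lc):
                    buf[buf_used + q] = cur[q]
                buf_used += lc
                pivot_owner[piv] = n_stored
                n_stored += 1
                pair_edge[n_pairs] = e
                pair_tri[n_pairs] = piv
                n_pairs += 1
                break
            # cur <- cur XOR stored column (symmetric difference of
            # ascending triangle-rank lists)
            s = starts[owner]
            ln = lens[owner]
            i = 0
            j = 0
            k = 0
            while i < lc and j < ln:
                a = cur[i]
                b = buf[s + j]
                if a < b:
                    tmp[k] = a
                    i += 1
                    k += 1
                elif b < a:
                    tmp[k] = b
                    j += 1
                    k += 1
                else:
                    i += 1
                    j += 1
            while i < lc:
                tmp[k] = cur[i]
                i += 1
                k += 1
            while j < ln:
                tmp[k] = buf[s + j]
                j += 1
                k += 1
            for q in range(k):
                cur[q] = tmp[q]
            lc = k
    return pair_edge[:n_pairs], pair_tri[:n_pairs]


@njit(cache=True)
def _reduce_direct(tri_rows, n_edges):  # pragma: no cover - jitted
    """Direct reduction of triangle boundary columns in filtration order."""
    m = tri_rows.shape[0]
    pivot_owner = np.full(n_edges, -1, np.int64)
    cap = 4 * m + 16
    buf = np.empty(cap, np.int64)
    starts = np.empty(n_edges, np.int64)
    lens = np.empty(n_edges, np.int64)
    n_stored = 0
    buf_used = 0
    pair_edge = np.empty(n_edges, np.int64)
    pair_tri = np.empty(n_edges, np.int64)
    n_pairs = 0
    cur = np.empty(n_edges, np.int64)
    tmp = np.empty(n_edges, np.int64)
    for t in range(m):
        lc = 3
        cur[0] = tri_rows[t, 0]
        cur[1] = tri_rows[t, 1]
        cur[2] = tri_rows[t, 2]
        while lc > 0:
            piv = cur[lc - 1]  # largest edge rank present
            owner = pivot_owner[piv]
            if owner == -1:
                if buf_used + lc > cap:
                    newcap = cap
                    while newcap < buf_used + lc:
                        newcap *= 2
                    nb = np.empty(newcap, np.int64)
                    nb[:buf_used] = buf[:buf_used]
                    buf = nb
                    cap = newcap
                starts[n_stored] = buf_used
                lens[n_stored] = lc
                for q in range(lc):
                    buf[buf_used + q] = cur[q]
                buf_used += lc
                pivot_owner[piv] = n_stored
                n_stored += 1
                pair_edge[n_pairs] = piv
                pair_tri[n_pairs] = t
                n_pairs += 1
                break
            s = starts[owner]
            ln = lens[owner]
            i = 0
            j = 0
            k = 0
            while i < lc and j < ln:
                a = cur[i]
                b = buf[s + j]
                if a < b:
                    tmp[k] = a
                    i += 1
                    k += 1
                elif b < a:
                    tmp[k] = b
                    j += 1
                    k += 1
                else:
                    i += 1
                    j += 1
            while i < lc:
                tmp[k] = cur[i]
                i += 1
                k += 1
            while j < ln:
                tmp[k] = buf[s + j]
                j += 1
                k += 1
            for q in range(k):
                cur[q] = tmp[q]
            lc = k
    return pair_edge[:n_pairs], pair_tri[:n_pairs]


def _triangles(adj, edge_rank, edge_w):
    """Enumerate triangles in deterministic filtration order."""
    m = _count_triangles(adj)
    if m == 0:
        return (np.empty((0, 3), dtype=np.int64), np.empty(0, dtype=np.float64))
    tri_rows = np.empty((m, 3), dtype=np.int64)
    tri_vals = np.empty(m, dtype=np.float64)
    _fill_triangles(adj, edge_rank, edge_w, tri_rows, tri_vals)
    # order by value; enumeration is vertex-lexicographic, so a stable
    # sort leaves ties in that deterministic order
    order = np.argsort(tri_vals, kind="stable")
    return np.ascontiguousarray(tri_rows[order]), tri_vals[order]


def h1_persistence_pairs(
    adj: np.ndarray,
    edge_rank: np.ndarray,
    edge_w: np.ndarray,
    ei: np.ndarray,
    ej: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Dimension-1 (birth, death) filtration values of a clique filtration.

    Parameters
    ----------
    adj
        ``(n, n)`` boolean adjacency of edges admitted to the filtration.
    edge_rank
        ``(n, n)`` int64 map from vertex pair to edge filtration rank
        (-1 where no edge).
    edge_w
        Edge weights indexed by rank, nondecreasing.
    ei, ej
        Edge endpoint vertices indexed by rank.

    Returns
    -------
    births, deaths
        Filtration values of paired edges and triangles (same length).
        Zero-persistence pairs are *not* filtered here.
    """
    n_edges = edge_w.shape[0]
    if n_edges < 3:
        empty = np.empty(0, dtype=float)
        return empty, empty
    tri_rows, tri_vals = _triangles(adj, edge_rank, edge_w)
    m = tri_rows.shape[0]
    if m == 0:
        empty = np.empty(0, dtype=float)
        return empty, empty
    # cofacet lists grouped by edge, triangle ranks ascending within each
    flat_tris, cof_off = _group_cofacets(tri_rows, np.int64(n_edges))
    skip = _kruskal_negative_edges(
        ei.astype(np.int64), ej.astype(np.int64), np.int64(adj.shape[0])
    )
    pair_edge, pair_tri = _coreduce(flat_tris, cof_off, np.int64(m), skip)
    return edge_w[pair_edge], tri_vals[pair_tri]


def reduce_triangle_boundary(
    adj: np.ndarray, edge_rank: np.ndarray, edge_w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Direct (homology-order) reduction; slow cross-check of the fast path."""
    n_edges = edge_w.shape[0]
    if n_edges < 3:
        empty = np.empty(0, dtype=float)
        return empty, empty
    tri_rows, tri_vals = _triangles(adj, edge_rank, edge_w)
    if tri_rows.shape[0] == 0:
        empty = np.empty(0, dtype=float)
        return empty, empty
    pair_edge, pair_tri = _reduce_direct(tri_rows, np.int64(n_edges))
    return edge_w[pair_edge], tri_vals[pair_tri]
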