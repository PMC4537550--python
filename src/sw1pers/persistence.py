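"""1-dimensional persistent homology of Vietoris–Rips filtrations.

The sliding-window pipeline reduces periodicity detection to a question about
the shape of a finite point cloud on the unit sphere: a periodic signal traces
a closed loop, and the prominence of that loop is read off the H1 persistence
diagram of the Rips filtration.  This module computes that diagram from a
distance matrix, restricted to simplices of dimension <= 2 (vertices enter at
scale 0, edges at their length, triangles at their longest edge), by boundary
matrix column reduction over a prime field.

Two equivalent reduction routes are implemented:

* ``field_char == 2`` (the default): column reduction of the anti-transposed
  boundary matrix — coboundary columns of edges taken in decreasing
  filtration order, against triangle-cofacet rows — with the clearing
  optimization (columns of negative edges, identified beforehand by a
  union-find sweep, are skipped because they provably reduce to zero).  By
  the anti-transposition theorem the pivots are exactly the persistence
  pairs of the ordinary reduction, but the columns stay short, so a cloud of
  a few hundred points reduces in milliseconds even though its filtration
  holds ~10^6 triangles.  Cofacets are enumerated on the fly from the
  distance matrix; no triangle list is ever materialized.
* odd primes: a plain sparse-column reduction of the triangle boundary in
  the homology direction, intended for small clouds and cross-checks.

Determinism: simplices are ordered by filtration value, then dimension, then
lexicographic vertex tuple; ties in edge length are broken the same way, and
the reduction is a fixed sequential algorithm, so the diagram is a pure
function of the distance matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PersistenceDiagram",
    "pairwise_distances",
    "coverage_radius",
    "rips_h1",
    "max_death",
    "DEFAULT_MAX_SCALE",
]

#: Default filtration cap: for pointwise-centered unit vectors every relevant
#: death is at most sqrt(3); the epsilon keeps the killing triangles inside.
DEFAULT_MAX_SCALE = math.sqrt(3.0) + 1e-6


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of H1 (birth, death) intervals over Z/p.

    ``intervals`` is a float array of shape (k, 2) with ``birth < death`` in
    every row; zero-persistence pairs are dropped at construction.  A cycle
    still alive at the filtration cap is reported censored at ``max_scale``
    and its row is flagged in ``censored``.
    """

    intervals: np.ndarray
    field_char: int = 2
    max_scale: float = DEFAULT_MAX_SCALE
    censored: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    dimension: int = 1

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        cens = np.asarray(self.censored, dtype=bool)
        if cens.shape[0] != iv.shape[0]:
            cens = np.zeros(iv.shape[0], dtype=bool)
        object.__setattr__(self, "censored", cens)
        if iv.size and not np.all(iv[:, 0] < iv[:, 1]):
            raise ValueError("every stored interval must satisfy birth < death")

    def __len__(self) -> int:
        return self.intervals.shape[0]


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix of a point cloud (rows = points).

    Symmetry is enforced exactly and the diagonal is zero, so downstream
    code may rely on ``dm == dm.T`` bit for bit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need a nonempty 2-d array of points")
    sq = np.sum(pts**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    np.maximum(d2, 0.0, out=d2)
    dm = np.sqrt(d2)
    dm = 0.5 * (dm + dm.T)
    np.fill_diagonal(dm, 0.0)
    return dm


def _check_dm(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(dm < 0):
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return dm


def coverage_radius(dm: np.ndarray) -> float:
    """Coverage radius b: the largest nearest-neighbour distance in the cloud.

    b bounds how finely the cloud samples its underlying shape; together with
    the maximal H1 death d it feeds the periodicity score.
    """
    dm = _check_dm(dm)
    n = dm.shape[0]
    if n < 2:
        raise ValueError("coverage radius needs at least 2 points")
    masked = dm + np.diag(np.full(n, np.inf))
    return float(np.max(np.min(masked, axis=1)))


@njit(cache=True)
def _union_find_positive(ei, ej, n):
    """Mark cycle-creating edges (processed in filtration order)."""
    parent = np.arange(n)
    positive = np.zeros(ei.shape[0], dtype=np.bool_)
    for e in range(ei.shape[0]):
        ri = ei[e]
        while parent[ri] != ri:
            parent[ri] = parent[parent[ri]]
            ri = parent[ri]
        rj = ej[e]
        while parent[rj] != rj:
            parent[rj] = parent[parent[rj]]
            rj = parent[rj]
        if ri == rj:
            positive[e] = True
        elif ri < rj:
            parent[rj] = ri
        else:
            parent[ri] = rj
    return positive


@njit(cache=True)
def _merge_arrays_z2(av, ac, bv, bc):
    """Symmetric difference of two columns over Z/2.

    Columns are parallel (value, code) arrays sorted ascending by
    (filtration value, vertex code); equal codes cancel.
    """
    na = av.shape[0]
    nb = bv.shape[0]
    ov = np.empty(na + nb, dtype=np.float64)
    oc = np.empty(na + nb, dtype=np.int64)
    ia = 0
    ib = 0
    m = 0
    while ia < na and ib < nb:
        if ac[ia] == bc[ib]:
            ia += 1
            ib += 1
        elif av[ia] < bv[ib] or (av[ia] == bv[ib] and ac[ia] < bc[ib]):
            ov[m] = av[ia]
            oc[m] = ac[ia]
            ia += 1
            m += 1
        else:
            ov[m] = bv[ib]
            oc[m] = bc[ib]
            ib += 1
            m += 1
    while ia < na:
        ov[m] = av[ia]
        oc[m] = ac[ia]
        ia += 1
        m += 1
    while ib < nb:
        ov[m] = bv[ib]
        oc[m] = bc[ib]
        ib += 1
        m += 1
    return ov[:m], oc[:m]


@njit(cache=True)
def _hpush(hv, hc, hs, v, c):
    """Push (v, c) onto a min-heap ordered by (value, code); grows arrays."""
    if hs == hv.shape[0]:
        nv = np.empty(2 * hs, dtype=np.float64)
        nc = np.empty(2 * hs, dtype=np.int64)
        nv[:hs] = hv
        nc[:hs] = hc
        hv = nv
        hc = nc
    i = hs
    hv[i] = v
    hc[i] = c
    while i > 0:
        p = (i - 1) // 2
        if hv[p] < hv[i] or (hv[p] == hv[i] and hc[p] <= hc[i]):
            break
        hv[p], hv[i] = hv[i], hv[p]
        hc[p], hc[i] = hc[i], hc[p]
        i = p
    return hv, hc, hs + 1


@njit(cache=True)
def _hpop(hv, hc, hs):
    """Pop the minimum (value, code) entry; caller checks hs > 0."""
    v = hv[0]
    c = hc[0]
    hs -= 1
    if hs > 0:
        hv[0] = hv[hs]
        hc[0] = hc[hs]
        i = 0
        while True:
            l = 2 * i + 1
            r = l + 1
            s = i
            if l < hs and (hv[l] < hv[s] or (hv[l] == hv[s] and hc[l] < hc[s])):
                s = l
            if r < hs and (hv[r] < hv[s] or (hv[r] == hv[s] and hc[r] < hc[s])):
                s = r
            if s == i:
                break
            hv[s], hv[i] = hv[i], hv[s]
            hc[s], hc[i] = hc[i], hc[s]
            i = s
    return v, c, hs


@njit(cache=True)
def _hpop_pivot(hv, hc, hs):
    """Pop entries, cancelling equal pairs mod 2, until an odd one survives.

    Returns (value, code, new_size, found).
    """
    while hs > 0:
        v, c, hs = _hpop(hv, hc, hs)
        if hs > 0 and hc[0] == c:
            _, _, hs = _hpop(hv, hc, hs)
            continue
        return v, c, hs, True
    return 0.0, np.int64(-1), hs, False


@njit(cache=True)
def _cofacets(e, ei, ej, ev, dm, max_scale, cv, cc):
    """Cofacet triangles of edge e as (value, code) arrays.

    Fills the scratch buffers ``cv``/``cc`` and returns the count; entries
    are unsorted.
    """
    n = dm.shape[0]
    i = ei[e]
    j = ej[e]
    base = ev[e]
    cnt = 0
    for k in range(n):
        if k == i or k == j:
            continue
        dik = dm[i, k]
        djk = dm[j, k]
        if dik > max_scale or djk > max_scale:
            continue
        v = base
        if dik > v:
            v = dik
        if djk > v:
            v = djk
        a = i
        b = j
        c = k
        if a > b:
            a, b = b, a
        if b > c:
            b, c = c, b
        if a > b:
            a, b = b, a
        cv[cnt] = v
        cc[cnt] = (a * n + b) * n + c
        cnt += 1
    return cnt


@njit(cache=True)
def _sorted_col(cv, cc, cnt):
    """Sort a scratch cofacet column ascending by (value, code)."""
    order = np.argsort(cv[:cnt], kind="mergesort")
    colv = cv[:cnt][order].copy()
    colc = cc[:cnt][order].copy()
    s = 0
    while s < cnt - 1:
        t = s + 1
        while t < cnt and colv[t] == colv[s]:
            t += 1
        if t - s > 1:
            sub = np.argsort(colc[s:t], kind="mergesort")
            colc[s:t] = colc[s:t][sub]
        s = t
    return colv, colc


@njit(cache=True)
def _reduce_dual_z2(ei, ej, ev, positive, dm, max_scale):
    """Dual (anti-transpose) Z/2 reduction yielding the (edge, triangle) pairs.

    Processes coboundary columns of the positive edges in decreasing
    filtration order; negative edges are cleared (their columns provably
    reduce to zero).  The pivot of a column is its earliest cofacet in the
    (value, lexicographic-code) simplex order.  Returns per-edge death values
    (the pivot triangle's filtration value), NaN where the edge stays
    unpaired (essential class under the cap).

    Pivot collisions are rare for these filtrations, so a freshly assembled
    column whose pivot slot is free is stored lazily as just its edge id; the
    full sorted column is materialized by re-enumerating cofacets only if a
    later chase actually has to add it.
    """
    n = dm.shape[0]
    n_edges = ei.shape[0]
    death = np.full(n_edges, np.nan)
    # open-addressing hash map: pivot triangle code -> stored column slot
    cap = 1
    while cap < 4 * n_edges:
        cap *= 2
    mask = cap - 1
    hkey = np.full(cap, -1, dtype=np.int64)
    hval = np.empty(cap, dtype=np.int64)
    lazy_edge = [np.int64(0) for _ in range(0)]  # typed empty list of int64
    mat_v = [np.empty(0, dtype=np.float64) for _ in range(0)]
    mat_c = [np.empty(0, dtype=np.int64) for _ in range(0)]
    cv = np.empty(n, dtype=np.float64)
    cc = np.empty(n, dtype=np.int64)
    for e in range(n_edges - 1, -1, -1):
        if not positive[e]:
            continue
        cnt = _cofacets(e, ei, ej, ev, dm, max_scale, cv, cc)
        if cnt == 0:
            continue
        # pivot of the fresh column without sorting it
        pv = cv[0]
        pcode = cc[0]
        for x in range(1, cnt):
            if cv[x] < pv or (cv[x] == pv and cc[x] < pcode):
                pv = cv[x]
                pcode = cc[x]
        h = (pcode * np.int64(0x9E3779B1)) & mask
        idx = -1
        while hkey[h] != -1:
            if hkey[h] == pcode:
                idx = hval[h]
                break
            h = (h + 1) & mask
        if idx == -1:
            hkey[h] = pcode
            hval[h] = len(lazy_edge)
            lazy_edge.append(np.int64(e))
            mat_v.append(np.empty(0, dtype=np.float64))
            mat_c.append(np.empty(0, dtype=np.int64))
            death[e] = pv
            continue
        # collision: chase by explicit sorted-array merging first (cheapest
        # for the typical short chase), falling back to a lazy heap column
        # when the chase runs long, so each stored-column addition then
        # costs only its own length, not the working column's
        colv, colc = _sorted_col(cv, cc, cnt)
        done = False
        while colv.shape[0] > 0 and colv.shape[0] < 4096:
            pcode = colc[0]
            h = (pcode * np.int64(0x9E3779B1)) & mask
            idx = -1
            while hkey[h] != -1:
                if hkey[h] == pcode:
                    idx = hval[h]
                    break
                h = (h + 1) & mask
            if idx == -1:
                hkey[h] = pcode
                hval[h] = len(lazy_edge)
                lazy_edge.append(np.int64(-1))
                mat_v.append(colv)
                mat_c.append(colc)
                death[e] = colv[0]
                done = True
                break
            if mat_v[idx].shape[0] == 0 and lazy_edge[idx] >= 0:
                cnt2 = _cofacets(lazy_edge[idx], ei, ej, ev, dm, max_scale, cv, cc)
                sv, sc = _sorted_col(cv, cc, cnt2)
                mat_v[idx] = sv
                mat_c[idx] = sc
            colv, colc = _merge_arrays_z2(colv, colc, mat_v[idx], mat_c[idx])
        if done or colv.shape[0] == 0:
            continue
        hv = np.empty(256, dtype=np.float64)
        hc = np.empty(256, dtype=np.int64)
        hs = 0
        for x in range(colv.shape[0]):
            hv, hc, hs = _hpush(hv, hc, hs, colv[x], colc[x])
        while True:
            pv, pcode, hs, found = _hpop_pivot(hv, hc, hs)
            if not found:
                break  # column vanished: essential class, death stays NaN
            h = (pcode * np.int64(0x9E3779B1)) & mask
            idx = -1
            while hkey[h] != -1:
                if hkey[h] == pcode:
                    idx = hval[h]
                    break
                h = (h + 1) & mask
            if idx == -1:
                # claim the pivot and store the fully reduced column
                outv = np.empty(hs + 1, dtype=np.float64)
                outc = np.empty(hs + 1, dtype=np.int64)
                outv[0] = pv
                outc[0] = pcode
                m2 = 1
                while True:
                    v2, c2, hs, found2 = _hpop_pivot(hv, hc, hs)
                    if not found2:
                        break
                    outv[m2] = v2
                    outc[m2] = c2
                    m2 += 1
                hkey[h] = pcode
                hval[h] = len(lazy_edge)
                lazy_edge.append(np.int64(-1))
                mat_v.append(outv[:m2].copy())
                mat_c.append(outc[:m2].copy())
                death[e] = pv
                break
            if mat_v[idx].shape[0] == 0 and lazy_edge[idx] >= 0:
                cnt2 = _cofacets(lazy_edge[idx], ei, ej, ev, dm, max_scale, cv, cc)
                sv, sc = _sorted_col(cv, cc, cnt2)
                mat_v[idx] = sv
                mat_c[idx] = sc
            sv = mat_v[idx]
            sc = mat_c[idx]
            # re-add the pivot itself: the stored column's head cancels it
            hv, hc, hs = _hpush(hv, hc, hs, pv, pcode)
            for x in range(sv.shape[0]):
                hv, hc, hs = _hpush(hv, hc, hs, sv[x], sc[x])
    return death


@njit(cache=True)
def _enumerate_triangles(eid, adj, ev_sorted):
    """All triangles i<j<k with pairwise edges in the filtration.

    Returns per-triangle boundary edge ids (in sorted-edge order) and the
    filtration value (longest edge).  Rows come out in lexicographic vertex
    order, so a stable sort by value reproduces the documented ordering.
    """
    n = adj.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n):
                if adj[i, k] and adj[j, k]:
                    count += 1
    edges = np.empty((count, 3), dtype=np.int64)
    vals = np.empty(count, dtype=np.float64)
    t = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n):
                if adj[i, k] and adj[j, k]:
                    a = eid[i, j]
                    b = eid[i, k]
                    c = eid[j, k]
                    v = ev_sorted[a]
                    if ev_sorted[b] > v:
                        v = ev_sorted[b]
                    if ev_sorted[c] > v:
                        v = ev_sorted[c]
                    edges[t, 0] = a
                    edges[t, 1] = b
                    edges[t, 2] = c
                    vals[t] = v
                    t += 1
    return edges, vals


def _reduce_modp(tri_edges: np.ndarray, tri_vals: np.ndarray, n_edges: int, p: int):
    """Sparse column reduction of the triangle boundary over Z/p (odd prime).

    Boundary of triangle (i<j<k) in oriented simplicial homology is
    [j,k] - [i,k] + [i,j]; rows of ``tri_edges`` carry (eid_ij, eid_ik,
    eid_jk) so the signs are (+1, -1, +1).  Homology direction, no clearing;
    meant for small clouds and cross-checks, not the 201-point pipeline.
    """
    death = np.full(n_edges, np.nan)
    low_col: dict[int, dict[int, int]] = {}
    for t in range(tri_edges.shape[0]):
        a, b, c = (int(x) for x in tri_edges[t])
        col = {a: 1 % p, b: (-1) % p, c: 1 % p}
        col = {k: v for k, v in col.items() if v}
        while col:
            piv = max(col)
            if piv not in low_col:
                inv = pow(col[piv], -1, p)
                col = {k: (v * inv) % p for k, v in col.items()}
                low_col[piv] = col
                death[piv] = tri_vals[t]
                break
            other = low_col[piv]
            f = col[piv]
            for k, v in other.items():
                col[k] = (col.get(k, 0) - f * v) % p
            col = {k: v for k, v in col.items() if v}
    return death


def _is_prime(p: int) -> bool:
    if p < 2:
        return False
    return all(p % q for q in range(2, int(p**0.5) + 1))


def rips_h1(
    dm: np.ndarray,
    max_scale: float | None = None,
    field_char: int = 2,
) -> PersistenceDiagram:
    """H1 persistence diagram of the Rips filtration of a distance matrix.

    Parameters
    ----------
    dm : square symmetric nonnegative array
        Distances between cloud points.
    max_scale : float, optional
        Filtration cap; simplices with value above it are excluded and
        still-alive cycles are reported censored at the cap.  Defaults to
        sqrt(3) + 1e-6, the bound satisfied by pointwise-normalized clouds.
    field_char : int
        Prime characteristic of the coefficient field (default 2).
    """
    dm = _check_dm(dm)
    if max_scale is None:
        max_scale = DEFAULT_MAX_SCALE
    if max_scale <= 0:
        raise ValueError("max_scale must be positive")
    if not _is_prime(int(field_char)):
        raise ValueError(f"field_char must be prime, got {field_char}")
    n = dm.shape[0]
    empty = PersistenceDiagram(
        np.zeros((0, 2)), field_char=field_char, max_scale=max_scale
    )
    if n < 3:
        return empty

    iu, ju = np.triu_indices(n, k=1)
    keep = dm[iu, ju] <= max_scale
    ei, ej, ev = iu[keep], ju[keep], dm[iu, ju][keep]
    if ei.size < 3:
        return empty
    # (i, j) pairs are generated lexicographically, so a stable sort by value
    # breaks ties lexicographically — the documented simplex order.
    order = np.argsort(ev, kind="stable")
    ei = ei[order].astype(np.int64)
    ej = ej[order].astype(np.int64)
    ev = ev[order]
    n_edges = ei.size

    positive = _union_find_positive(ei, ej, n)

    if field_char == 2:
        death = _reduce_dual_z2(ei, ej, ev, positive, dm, float(max_scale))
    else:
        eid = np.full((n, n), -1, dtype=np.int64)
        eid[ei, ej] = np.arange(n_edges)
        eid[ej, ei] = np.arange(n_edges)
        adj = eid >= 0
        tri_edges, tri_vals = _enumerate_triangles(eid, adj, ev)
        if tri_edges.shape[0] == 0:
            death = np.full(n_edges, np.nan)
        else:
            t_order = np.argsort(tri_vals, kind="stable")
            death = _reduce_modp(
                tri_edges[t_order], tri_vals[t_order], n_edges, int(field_char)
            )

    births, deaths, cens = [], [], []
    for e in np.flatnonzero(positive):
        d = death[e]
        if np.isnan(d):
            births.append(float(ev[e]))
            deaths.append(float(max_scale))
            cens.append(True)
        elif d > ev[e]:
            births.append(float(ev[e]))
            deaths.append(float(d))
            cens.append(False)
    if not births:
        return empty
    iv = np.column_stack([births, deaths])
    return PersistenceDiagram(
        iv, field_char=field_char, max_scale=max_scale, censored=np.array(cens)
    )


def max_death(diagram: PersistenceDiagram) -> float | None:
    """Largest death in the diagram, or None when it is empty."""
    if len(diagram) == 0:
        return None
    return float(np.max(diagram.intervals[:, 1]))
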