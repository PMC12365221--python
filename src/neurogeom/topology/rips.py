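"""Vietoris-Rips persistent homology over Z/2, dimensions 0-2.

The filtration is built from the pairwise distance matrix up to a
threshold (default: the enclosing radius ``min_i max_j d_ij``, beyond
which the complex is a cone and no positive-dimensional class survives).

H0 comes from a union-find pass over sorted edges.  H1/H2 use the
persistent-cohomology formulation: for each dimension ``p`` the
coboundary columns of the ``p``-simplices are reduced in decreasing
filtration order with implicit cofacet enumeration, a zero-persistence
("emergent") pair shortcut, and clearing of simplices already paired in
the previous dimension.  This is the standard algorithmic recipe that
makes Rips persistence tractable: columns are indexed by ``p``-simplices
rather than by the far more numerous ``(p+1)``-simplices, and most
columns pair immediately without any column additions.

An optional net-pruning approximation (``sparse_eps``) greedily removes
points closer than ``sparse_eps`` times the cloud's mean nearest-neighbor
spacing; by Hausdorff stability of Rips filtrations this perturbs bar
endpoints by at most twice the pruning radius.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import Dict
from numba.types import int64
from scipy.spatial.distance import pdist, squareform

__all__ = ["rips_barcode", "enclosing_radius", "net_prune"]


def enclosing_radius(D: np.ndarray) -> float:
    """Radius at which the complex becomes a cone over some vertex."""
    return float(np.min(np.max(D, axis=1)))


def _binom_table(n: int, kmax: int = 4) -> np.ndarray:
    B = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    B[:, 0] = 1
    for i in range(1, n + 1):
        for k in range(1, kmax + 1):
            B[i, k] = B[i - 1, k - 1] + B[i - 1, k]
    return B


@njit(cache=True)
def _enum_triangles(D, thresh):
    n = D.shape[0]
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > thresh:
                continue
            for k in range(j + 1, n):
                if D[i, k] <= thresh and D[j, k] <= thresh:
                    cnt += 1
    tri = np.empty((cnt, 3), np.int32)
    diam = np.empty(cnt, np.float64)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = D[i, j]
            if dij > thresh:
                continue
            for k in range(j + 1, n):
                dik = D[i, k]
                djk = D[j, k]
                if dik <= thresh and djk <= thresh:
                    tri[c, 0] = i
                    tri[c, 1] = j
                    tri[c, 2] = k
                    d = dij
                    if dik > d:
                        d = dik
                    if djk > d:
                        d = djk
                    diam[c] = d
                    c += 1
    return tri, diam


@njit(cache=True)
def _union_find_h0(edges_i, edges_j, n):
    """Merge flags over sorted edges and final component count."""
    parent = np.arange(n)
    merged = np.zeros(len(edges_i), np.bool_)
    ncomp = n
    for r in range(len(edges_i)):
        a = edges_i[r]
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        b = edges_j[r]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a != b:
            parent[a] = b
            merged[r] = True
            ncomp -= 1
    return merged, ncomp


@njit(cache=True, inline="always")
def _cofacet_index(verts, w, p1, binom):
    """Combinatorial index of the cofacet of a p-simplex (p1 = p + 1
    vertices) obtained by inserting vertex w."""
    idx = np.int64(0)
    pos = 0
    k = 1
    for t in range(p1):
        if verts[t] < w:
            idx += binom[verts[t], k]
            k += 1
        else:
            if pos == 0:
                idx += binom[w, k]
                k += 1
                pos = 1
            idx += binom[verts[t], k]
            k += 1
    if pos == 0:
        idx += binom[w, k]
    return idx


@njit(cache=True, inline="always")
def _heap_push(hd, hi, size, d, ix):
    hd[size] = d
    hi[size] = ix
    c = size
    while c > 0:
        par = (c - 1) >> 1
        if hd[par] > hd[c] or (hd[par] == hd[c] and hi[par] > hi[c]):
            hd[par], hd[c] = hd[c], hd[par]
            hi[par], hi[c] = hi[c], hi[par]
            c = par
        else:
            break
    return size + 1


@njit(cache=True, inline="always")
def _heap_pop(hd, hi, size):
    size -= 1
    hd[0] = hd[size]
    hi[0] = hi[size]
    c = 0
    while True:
        l = 2 * c + 1
        r = l + 1
        best = c
        if l < size and (
            hd[l] < hd[best] or (hd[l] == hd[best] and hi[l] < hi[best])
        ):
            best = l
        if r < size and (
            hd[r] < hd[best] or (hd[r] == hd[best] and hi[r] < hi[best])
        ):
            best = r
        if best == c:
            break
        hd[best], hd[c] = hd[c], hd[best]
        hi[best], hi[c] = hi[c], hi[best]
        c = best
    return size


@njit(cache=True)
def _coh_reduce(verts, diam, order, cleared, D, thresh, binom):
    """Cohomology reduction for one dimension.

    verts : (S, p+1) vertex ids of the p-simplices
    diam : (S,) diameters
    order : column processing order (decreasing filtration)
    cleared : (S,) columns to skip (paired in dimension p-1)

    Returns
    -------
    pair_birth, pair_death : persistence pairs (only death > birth)
    essential : diameters of essential p-classes
    pivot_keys : combinatorial indices of the (p+1)-pivot cofacets
                 (for clearing in the next dimension)
    """
    S, p1 = verts.shape
    n = D.shape[0]

    pivots = Dict.empty(int64, int64)  # cofacet cindex -> stored column slot
    # stored columns: either implicit (re-enumerate cofacets of a simplex)
    # or explicit pooled entries
    col_src = np.full(S + 16, -1, np.int64)  # implicit source simplex row
    col_start = np.full(S + 16, -1, np.int64)
    col_len = np.zeros(S + 16, np.int64)
    n_cols = 0
    pool_i = np.empty(4 * S + 64, np.int64)
    pool_d = np.empty(4 * S + 64, np.float64)
    pool_top = 0

    heap_d = np.empty(1024, np.float64)
    heap_i = np.empty(1024, np.int64)

    cof_d = np.empty(n, np.float64)
    cof_i = np.empty(n, np.int64)

    pair_birth = np.empty(S, np.float64)
    pair_death = np.empty(S, np.float64)
    n_pairs = 0
    essential = np.empty(S, np.float64)
    n_ess = 0
    pivot_keys = np.empty(S, np.int64)
    n_piv = 0

    vbuf = np.empty(p1, np.int32)

    for oi in range(len(order)):
        ci = order[oi]
        if cleared[ci]:
            continue
        for t in range(p1):
            vbuf[t] = verts[ci, t]
        dsig = diam[ci]
        # enumerate cofacets
        ncof = 0
        min_d = np.inf
        min_i = np.int64(-1)
        for w in range(n):
            ok = True
            dmax = dsig
            for t in range(p1):
                if w == vbuf[t]:
                    ok = False
                    break
                dv = D[w, vbuf[t]]
                if dv > thresh:
                    ok = False
                    break
                if dv > dmax:
                    dmax = dv
            if not ok:
                continue
            cix = _cofacet_index(vbuf, w, p1, binom)
            cof_d[ncof] = dmax
            cof_i[ncof] = cix
            ncof += 1
            if dmax < min_d or (dmax == min_d and cix < min_i):
                min_d = dmax
                min_i = cix
        if ncof == 0:
            essential[n_ess] = dsig
            n_ess += 1
            continue
        # emergent zero-persistence pair shortcut
        if min_d == dsig and min_i not in pivots:
            pivots[min_i] = n_cols
            col_src[n_cols] = ci  # implicit column
            pivot_keys[n_piv] = min_i
            n_piv += 1
            n_cols += 1
            continue
        # general reduction with a working min-heap
        hsize = 0
        need = ncof
        while need > len(heap_d):
            heap_d = np.empty(2 * len(heap_d), np.float64)
            heap_i = np.empty(len(heap_d), np.int64)
        for t in range(ncof):
            hsize = _heap_push(heap_d, heap_i, hsize, cof_d[t], cof_i[t])
        while True:
            # pop with Z/2 cancellation
            piv_d = np.nan
            piv_i = np.int64(-1)
            while hsize > 0:
                d0 = heap_d[0]
                i0 = heap_i[0]
                hsize = _heap_pop(heap_d, heap_i, hsize)
                if hsize > 0 and heap_i[0] == i0 and heap_d[0] == d0:
                    hsize = _heap_pop(heap_d, heap_i, hsize)  # cancel pair
                else:
                    piv_d = d0
                    piv_i = i0
                    break
            if piv_i == -1:
                essential[n_ess] = dsig
                n_ess += 1
                break
            if piv_i in pivots:
                slot = pivots[piv_i]
                # push back the popped pivot, then XOR the stored column
                hsize = _heap_push(heap_d, heap_i, hsize, piv_d, piv_i)
                if col_src[slot] >= 0:
                    src = col_src[slot]
                    dsrc = diam[src]
                    ncof2 = 0
                    for w in range(n):
                        ok = True
                        dmax = dsrc
                        for t in range(p1):
                            vv = verts[src, t]
                            if w == vv:
                                ok = False
                                break
                            dv = D[w, vv]
                            if dv > thresh:
                                ok = False
                                break
                            if dv > dmax:
                                dmax = dv
                        if not ok:
                            continue
                        cix = _cofacet_index(verts[src], w, p1, binom)
                        while hsize + 1 > len(heap_d):
                            nh_d = np.empty(2 * len(heap_d), np.float64)
                            nh_i = np.empty(len(nh_d), np.int64)
                            nh_d[:hsize] = heap_d[:hsize]
                            nh_i[:hsize] = heap_i[:hsize]
                            heap_d = nh_d
                            heap_i = nh_i
                        hsize = _heap_push(heap_d, heap_i, hsize, dmax, cix)
                        ncof2 += 1
                else:
                    st = col_start[slot]
                    ln = col_len[slot]
                    while hsize + ln > len(heap_d):
                        nh_d = np.empty(2 * len(heap_d), np.float64)
                        nh_i = np.empty(len(nh_d), np.int64)
                        nh_d[:hsize] = heap_d[:hsize]
                        nh_i[:hsize] = heap_i[:hsize]
                        heap_d = nh_d
                        heap_i = nh_i
                    for t in range(ln):
                        hsize = _heap_push(
                            heap_d, heap_i, hsize, pool_d[st + t], pool_i[st + t]
                        )
            else:
                # new pivot: record pair, store drained column explicitly
                if piv_d > dsig:
                    pair_birth[n_pairs] = dsig
                    pair_death[n_pairs] = piv_d
                    n_pairs += 1
                pivots[piv_i] = n_cols
                pivot_keys[n_piv] = piv_i
                n_piv += 1
                # drain remaining entries (canonical reduced column)
                tmp_d = np.empty(hsize + 1, np.float64)
                tmp_i = np.empty(hsize + 1, np.int64)
                nt = 0
                tmp_d[nt] = piv_d
                tmp_i[nt] = piv_i
                nt += 1
                while hsize > 0:
                    d0 = heap_d[0]
                    i0 = heap_i[0]
                    hsize = _heap_pop(heap_d, heap_i, hsize)
                    if hsize > 0 and heap_i[0] == i0 and heap_d[0] == d0:
                        hsize = _heap_pop(heap_d, heap_i, hsize)
                    else:
                        tmp_d[nt] = d0
                        tmp_i[nt] = i0
                        nt += 1
                while pool_top + nt > len(pool_i):
                    np_i = np.empty(2 * len(pool_i), np.int64)
                    np_d = np.empty(len(np_i), np.float64)
                    np_i[:pool_top] = pool_i[:pool_top]
                    np_d[:pool_top] = pool_d[:pool_top]
                    pool_i = np_i
                    pool_d = np_d
                pool_i[pool_top : pool_top + nt] = tmp_i[:nt]
                pool_d[pool_top : pool_top + nt] = tmp_d[:nt]
                col_start[n_cols] = pool_top
                col_len[n_cols] = nt
                pool_top += nt
                if n_cols + 1 >= len(col_src):
                    nc_src = np.full(2 * len(col_src), -1, np.int64)
                    nc_start = np.full(len(nc_src), -1, np.int64)
                    nc_len = np.zeros(len(nc_src), np.int64)
                    nc_src[: n_cols + 1] = col_src[: n_cols + 1]
                    nc_start[: n_cols + 1] = col_start[: n_cols + 1]
                    nc_len[: n_cols + 1] = col_len[: n_cols + 1]
                    col_src = nc_src
                    col_start = nc_start
                    col_len = nc_len
                n_cols += 1
                break
    return (
        pair_birth[:n_pairs],
        pair_death[:n_pairs],
        essential[:n_ess],
        pivot_keys[:n_piv],
    )


def net_prune(X: np.ndarray, radius: float) -> np.ndarray:
    """Greedy net: keep points pairwise farther apart than ``radius``."""
    D = squareform(pdist(X))
    n = len(X)
    keep = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    for i in range(n):
        if alive[i]:
            keep[i] = True
            alive &= D[i] > radius
            alive[i] = False
    return X[keep]


def rips_barcode(
    X: np.ndarray,
    max_dim: int = 2,
    thresh: float | None = None,
    sparse_eps: float = 0.0,
    metric_input: bool = False,
) -> dict[int, np.ndarray]:
    """Persistence intervals of the Vietoris-Rips filtration of a cloud.

    Parameters
    ----------
    X : (n, d) point cloud, or (n, n) distance matrix when ``metric_input``.
    max_dim : largest homology dimension (0, 1 or 2).
    thresh : filtration cap; ``None`` uses the enclosing radius.  Bars
        still alive at the cap are reported with death ``inf``.
    sparse_eps : optional net-pruning factor (times the mean
        nearest-neighbor spacing); 0 disables pruning.

    Returns
    -------
    dict mapping dimension to an ``(n_bars, 2)`` array of (birth, death).
    """
    X = np.asarray(X, dtype=float)
    if metric_input:
        D = np.array(X, dtype=float)
    else:
        if len(X) < 1:
            raise ValueError("empty point cloud")
        if sparse_eps > 0 and len(X) > 2:
            Dfull = squareform(pdist(X))
            np.fill_diagonal(Dfull, np.inf)
            nn = np.min(Dfull, axis=1)
            X = net_prune(X, sparse_eps * float(np.mean(nn)))
        D = squareform(pdist(X))
    n = D.shape[0]
    if max_dim > 2:
        raise ValueError("homology implemented up to dimension 2")
    if thresh is None:
        thresh = enclosing_radius(D) if n > 1 else 0.0

    bars: dict[int, np.ndarray] = {}
    if n == 1:
        bars[0] = np.array([[0.0, np.inf]])
        for d in range(1, max_dim + 1):
            bars[d] = np.empty((0, 2))
        return bars

    binom = _binom_table(n + 1)

    iu, ju = np.triu_indices(n, 1)
    ed = D[iu, ju]
    keep = ed <= thresh
    iu, ju, ed = iu[keep].astype(np.int64), ju[keep].astype(np.int64), ed[keep]
    eorder = np.argsort(ed, kind="stable")
    merged, ncomp = _union_find_h0(iu[eorder], ju[eorder], n)
    h0 = [(0.0, float(dv)) for dv in ed[eorder][merged]]
    h0 += [(0.0, np.inf)] * int(ncomp)
    bars[0] = np.array(h0) if h0 else np.empty((0, 2))
    if max_dim == 0:
        return bars

    # --- dimension 1 ---------------------------------------------------
    everts = np.column_stack([iu, ju]).astype(np.int32)
    ecidx = binom[ju, 2] + iu  # combinatorial index of each edge
    # process in decreasing (diam, cindex); cleared = merging edges
    key = np.lexsort((ecidx, ed))[::-1]
    cleared1 = np.zeros(len(ed), dtype=bool)
    cleared1[eorder[merged]] = True
    pb1, pd1, ess1, piv1 = _coh_reduce(
        everts, ed, key.astype(np.int64), cleared1, D, thresh, binom
    )
    h1 = [(float(b), float(d)) for b, d in zip(pb1, pd1)]
    h1 += [(float(b), np.inf) for b in ess1]
    bars[1] = np.array(h1) if h1 else np.empty((0, 2))
    if max_dim == 1:
        return bars

    # --- dimension 2 ---------------------------------------------------
    tri, tdi = _enum_triangles(D, thresh)
    if len(tri) == 0:
        bars[2] = np.empty((0, 2))
        return bars
    t64 = tri.astype(np.int64)
    tcidx = binom[t64[:, 2], 3] + binom[t64[:, 1], 2] + t64[:, 0]
    cleared2 = np.isin(tcidx, piv1)
    key2 = np.lexsort((tcidx, tdi))[::-1]
    pb2, pd2, ess2, _ = _coh_reduce(
        tri, tdi, key2.astype(np.int64), cleared2, D, thresh, binom
    )
    h2 = [(float(b), float(d)) for b, d in zip(pb2, pd2)]
    h2 += [(float(b), np.inf) for b in ess2]
    bars[2] = np.array(h2) if h2 else np.empty((0, 2))
    return bars
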