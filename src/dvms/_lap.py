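"""Compiled linear-assignment kernels for the sampler's inner loop.

A dense O(n^3) shortest-augmenting-path (Hungarian with potentials) solver
and a batched tile-membership resolver, both numba-compiled.  The resolver
mirrors the exact logic of :mod:`dvms.permutations` except that an odd
optimal assignment is repaired by the cheapest single target swap (exact in
almost all cases); folded positions are re-verified by the caller against
the exact predicate, so a rare suboptimal repair can only turn a fold into
a rejection, never corrupt tile containment.
"""

import numpy as np
from numba import njit

_INF = 1e30


@njit(cache=True)
def _lap(C):
    """Minimum-cost assignment of square matrix C; returns (perm, cost)
    with perm[i] the column assigned to row i."""
    n = C.shape[0]
    u = np.zeros(n + 1)
    v = np.zeros(n + 1)
    p = np.zeros(n + 1, np.int64)
    way = np.zeros(n + 1, np.int64)
    for i in range(1, n + 1):
        p[0] = i
        j0 = 0
        minv = np.full(n + 1, _INF)
        used = np.zeros(n + 1, np.bool_)
        while True:
            used[j0] = True
            i0 = p[j0]
            delta = _INF
            j1 = -1
            for j in range(1, n + 1):
                if not used[j]:
                    cur = C[i0 - 1, j - 1] - u[i0] - v[j]
                    if cur < minv[j]:
                        minv[j] = cur
                        way[j] = j0
                    if minv[j] < delta:
                        delta = minv[j]
                        j1 = j
            for j in range(n + 1):
                if used[j]:
                    u[p[j]] += delta
                    v[j] -= delta
                else:
                    minv[j] -= delta
            j0 = j1
            if p[j0] == 0:
                break
        while True:
            j1 = way[j0]
            p[j0] = p[j1]
            j0 = j1
            if j0 == 0:
                break
    perm = np.empty(n, np.int64)
    cost = 0.0
    for j in range(1, n + 1):
        perm[p[j] - 1] = j - 1
    for i in range(n):
        cost += C[i, perm[i]]
    return perm, cost


@njit(cache=True)
def _sign(p):
    n = len(p)
    seen = np.zeros(n, np.bool_)
    s = 1
    for i in range(n):
        if seen[i]:
            continue
        j = i
        length = 0
        while not seen[j]:
            seen[j] = True
            j = p[j]
            length += 1
        if length % 2 == 0:
            s = -s
    return s


@njit(cache=True)
def _cost_matrix(x, site, lo, hi, C):
    n = hi - lo
    for i in range(n):
        for j in range(n):
            d0 = x[lo + i, 0] - site[lo + j, 0]
            d1 = x[lo + i, 1] - site[lo + j, 1]
            d2 = x[lo + i, 2] - site[lo + j, 2]
            C[i, j] = d0 * d0 + d1 * d1 + d2 * d2


@njit(cache=True)
def _best_even_swap(C, perm, cost):
    """Cheapest single target swap making an odd assignment even (in place).
    Returns the repaired cost; perm is modified."""
    n = len(perm)
    best = _INF
    bi = bj = -1
    for i in range(n):
        for j in range(i + 1, n):
            d = C[i, perm[j]] + C[j, perm[i]] - C[i, perm[i]] - C[j, perm[j]]
            if d < best:
                best = d
                bi, bj = i, j
    if bi >= 0:
        t = perm[bi]
        perm[bi] = perm[bj]
        perm[bj] = t
        return cost + best
    return _INF


@njit(cache=True)
def resolve_batch(X, sites, na, tie_tol=1e-12):
    """Tile membership / nearest even image for a batch of configurations.

    X: (K, N, 3); sites: (M, N, 3).  Returns (inside (K,), owner (K,),
    perms (K, N)): where inside, owner is the owning site and perms the
    identity; where not, perms[k] is the (swap-repaired) best even
    permutation of sites[owner] and folding X[k] by it should re-enter the
    tile.
    """
    K, N = X.shape[0], X.shape[1]
    M = sites.shape[0]
    nb = N - na
    inside = np.zeros(K, np.bool_)
    owner = np.zeros(K, np.int64)
    perms = np.empty((K, N), np.int64)
    Ca = np.empty((na, na))
    Cb = np.empty((nb, nb))
    best_perm = np.empty(N, np.int64)
    for k in range(K):
        best_cost = _INF
        best_m = 0
        id_best = _INF
        id_m = 0
        for m in range(M):
            idc = 0.0
            for i in range(N):
                d0 = X[k, i, 0] - sites[m, i, 0]
                d1 = X[k, i, 1] - sites[m, i, 1]
                d2 = X[k, i, 2] - sites[m, i, 2]
                idc += d0 * d0 + d1 * d1 + d2 * d2
            if idc < id_best:
                id_best = idc
                id_m = m
            _cost_matrix(X[k], sites[m], 0, na, Ca)
            _cost_matrix(X[k], sites[m], na, N, Cb)
            if na > 0:
                pa, ca = _lap(Ca[:na, :na])
                sa = _sign(pa)
            else:
                pa = np.empty(0, np.int64)
                ca = 0.0
                sa = 1
            if nb > 0:
                pb, cb = _lap(Cb[:nb, :nb])
                sb = _sign(pb)
            else:
                pb = np.empty(0, np.int64)
                cb = 0.0
                sb = 1
            cost = ca + cb
            if sa * sb == -1:
                # repair within whichever spin is cheaper
                ca2 = _INF
                cb2 = _INF
                pa2 = pa.copy()
                pb2 = pb.copy()
                if na >= 2:
                    ca2 = _best_even_swap(Ca[:na, :na], pa2, ca)
                if nb >= 2:
                    cb2 = _best_even_swap(Cb[:nb, :nb], pb2, cb)
                if ca2 + cb <= ca + cb2:
                    pa = pa2
                    cost = ca2 + cb
                else:
                    pb = pb2
                    cost = ca + cb2
            if cost < best_cost:
                best_cost = cost
                best_m = m
                for i in range(na):
                    best_perm[i] = pa[i]
                for i in range(nb):
                    best_perm[na + i] = na + pb[i]
        if id_best <= best_cost + tie_tol:
            inside[k] = True
            owner[k] = id_m
            for i in range(N):
                perms[k, i] = i
        else:
            inside[k] = False
            owner[k] = best_m
            for i in range(N):
                perms[k, i] = best_perm[i]
    return inside, owner, perms
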