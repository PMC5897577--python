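"""Same-sign permutations and the Voronoi tile-membership test.

A wavefunction tile is bounded by the Voronoi tessellation of the images of
its site x-bar under like-spin permutations of even combined parity (the
"same-sign" permutations, which leave Psi unchanged).  A configuration
belongs to a tile when it is at least as close to the identity image of that
site as to any same-sign image of any site.

The nearest-image search runs one optimal linear assignment per spin
followed by a parity repair (cheapest single target swap within either
spin); an exhaustive enumeration path serves as oracle for small electron
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _itperms
import math

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SpinPermutation", "NearestImageResult", "permutation_sign",
    "enumerate_same_sign_permutations", "nearest_same_sign_image", "in_tile",
    "apply_permutation", "fold_into_tile",
]

_TIE_TOL = 1e-12  # squared-bohr slack under which identity wins a tie


def permutation_sign(perm) -> int:
    """Parity (+1/-1) of a permutation array, via cycle decomposition."""
    p = np.asarray(perm, dtype=int)
    n = len(p)
    if n and (p.min() < 0 or p.max() >= n or len(np.unique(p)) != n):
        raise ValueError("not a permutation")
    seen = np.zeros(n, dtype=bool)
    sign = 1
    for i in range(n):
        if seen[i]:
            continue
        j, length = i, 0
        while not seen[j]:
            seen[j] = True
            j = p[j]
            length += 1
        if length % 2 == 0:
            sign = -sign
    return sign


@dataclass(frozen=True)
class SpinPermutation:
    """A like-spin permutation pair P = (P_alpha, P_beta).

    Acting on a configuration x, electron i of spin sigma is matched with
    site electron ``perm_sigma[i]``.
    """

    alpha: tuple
    beta: tuple

    def __post_init__(self):
        object.__setattr__(self, "alpha", tuple(int(i) for i in self.alpha))
        object.__setattr__(self, "beta", tuple(int(i) for i in self.beta))

    @property
    def sign(self) -> int:
        return permutation_sign(self.alpha) * permutation_sign(self.beta)

    @property
    def is_identity(self) -> bool:
        return (self.alpha == tuple(range(len(self.alpha)))
                and self.beta == tuple(range(len(self.beta))))

    def as_array(self) -> np.ndarray:
        na = len(self.alpha)
        return np.concatenate([np.asarray(self.alpha, int),
                               na + np.asarray(self.beta, int)])


@dataclass
class NearestImageResult:
    permutation: SpinPermutation
    squared_distance: float
    is_identity: bool
    site_index: int = 0


def identity_permutation(n_alpha, n_beta) -> SpinPermutation:
    return SpinPermutation(tuple(range(n_alpha)), tuple(range(n_beta)))


def enumerate_same_sign_permutations(n_alpha: int, n_beta: int,
                                     limit: int = 10 ** 6):
    """All sign +1 like-spin permutations; exactly n_a! n_b!/2 of them when
    either spin has >= 2 electrons.  Oracle use only - guarded by ``limit``."""
    total = math.factorial(n_alpha) * math.factorial(n_beta)
    if total > limit:
        raise ValueError(
            f"{total} permutations exceed the enumeration guard ({limit}); "
            "use the assignment-based nearest-image search")
    out = []
    for pa in _itperms(range(n_alpha)):
        sa = permutation_sign(pa)
        for pb in _itperms(range(n_beta)):
            if sa * permutation_sign(pb) == 1:
                out.append(SpinPermutation(pa, pb))
    return out


def apply_permutation(x: np.ndarray, perm: SpinPermutation) -> np.ndarray:
    """Relabel electrons of x so that electron i moves to slot perm[i].

    The result y satisfies y[perm[i]] = x[i]; for a sign +1 permutation,
    Psi(y) = Psi(x).
    """
    p = perm.as_array()
    y = np.empty_like(x)
    y[p] = x
    return y


def _spin_cost(x, site, lo, hi):
    d = x[lo:hi, None, :] - site[None, lo:hi, :]
    return np.einsum("ijk,ijk->ij", d, d)


_BIG = 1e100


def _murty_even(C, na, parity=1):
    """Exact minimum-cost fixed-parity assignment on a combined cost matrix.

    ``C`` is block diagonal over the alpha (first ``na``) and beta rows with
    _BIG in the cross blocks, so any finite assignment factorises per spin.
    Assignments are enumerated in increasing cost (Murty ranking); the first
    one whose parity equals ``parity`` is the optimum.
    """
    import heapq
    n = len(C)

    def solve(M):
        r, c = linear_sum_assignment(M)
        cost = M[r, c].sum()
        return (None if cost >= _BIG / 2 else cost), c

    cost0, p0 = solve(C)
    if cost0 is None:
        raise ValueError("no feasible assignment")
    counter = 0
    heap = [(cost0, counter, C, p0)]
    while heap:
        cost, _, M, p = heapq.heappop(heap)
        if permutation_sign(p) == parity:
            return p, cost
        # partition: force p[:k], forbid p[k]
        forced = M
        for k in range(n):
            child = forced.copy()
            child[k, p[k]] = _BIG
            ccost, cp = solve(child)
            if ccost is not None:
                counter += 1
                heapq.heappush(heap, (ccost, counter, child, cp))
            # now force row k to p[k] for subsequent children
            nxt = forced.copy()
            nxt[k, :] = _BIG
            nxt[:, p[k]] = _BIG
            nxt[k, p[k]] = M[k, p[k]]
            forced = nxt
    raise ValueError("no even-parity assignment exists")


def _best_parity_assignment(Ca, Cb, parity=1):
    """Minimum-cost assignment of fixed combined parity.

    Per-spin optimal assignments first; if their combined parity is wrong,
    an exact ranked-assignment (Murty) search over the combined
    block-diagonal cost matrix finds the constrained optimum.
    Returns (perm_alpha, perm_beta, cost).
    """
    pa = linear_sum_assignment(Ca)[1] if Ca.size else np.empty(0, int)
    pb = linear_sum_assignment(Cb)[1] if Cb.size else np.empty(0, int)
    cost = (Ca[np.arange(len(pa)), pa].sum() if len(pa) else 0.0) + \
           (Cb[np.arange(len(pb)), pb].sum() if len(pb) else 0.0)
    if permutation_sign(pa) * permutation_sign(pb) == parity:
        return pa, pb, cost
    na, nb = len(pa), len(pb)
    if na + nb < 2:
        raise ValueError("requested parity unreachable with a single "
                         "electron")
    C = np.full((na + nb, na + nb), _BIG)
    if na:
        C[:na, :na] = Ca
    if nb:
        C[na:, na:] = Cb
    p, cost = _murty_even(C, na, parity)
    return p[:na], p[na:] - na, float(cost)


def _best_even_assignment(Ca, Cb):
    """Minimum-cost assignment of combined even parity."""
    return _best_parity_assignment(Ca, Cb, 1)


def nearest_same_sign_image(x, site_positions, n_alpha, n_beta,
                            method="assignment") -> NearestImageResult:
    """Sign +1 permutation P minimising ||x - P o site||^2.

    Ties with the identity (within 1e-12 bohr^2) resolve to the identity, so
    a boundary configuration counts as inside.  ``method`` is "assignment"
    (linear assignment + parity repair) or "enumerate" (exhaustive oracle).
    """
    x = np.asarray(x, float)
    site = np.asarray(site_positions, float)
    if x.shape != site.shape or x.shape[0] != n_alpha + n_beta:
        raise ValueError("configuration/site shape mismatch")
    Ca = _spin_cost(x, site, 0, n_alpha)
    Cb = _spin_cost(x, site, n_alpha, n_alpha + n_beta)
    id_cost = float(np.trace(Ca) + np.trace(Cb))
    if method == "enumerate":
        best_perm, best_cost = None, np.inf
        for perm in enumerate_same_sign_permutations(n_alpha, n_beta):
            c = Ca[np.arange(n_alpha), perm.alpha].sum() if n_alpha else 0.0
            c += Cb[np.arange(n_beta), perm.beta].sum() if n_beta else 0.0
            if c < best_cost - 1e-15:
                best_perm, best_cost = perm, c
    elif method == "assignment":
        pa, pb, best_cost = _best_even_assignment(Ca, Cb)
        best_perm = SpinPermutation(tuple(pa), tuple(pb))
    else:
        raise ValueError(f"unknown method {method!r}")
    if id_cost <= best_cost + _TIE_TOL:
        ident = identity_permutation(n_alpha, n_beta)
        return NearestImageResult(ident, id_cost, True)
    return NearestImageResult(best_perm, float(best_cost),
                              best_perm.is_identity)


def in_tile(x, sites, n_alpha, n_beta, method="assignment"):
    """(inside, owning site index) for a configuration against >= 1 sites.

    Inside means the global nearest same-sign image over all sites is the
    identity image of some site (boundaries count as inside).  The owning
    index is the site achieving the global minimum.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    results = [nearest_same_sign_image(x, s, n_alpha, n_beta, method)
               for s in sites]
    costs = np.array([r.squared_distance for r in results])
    ids = np.array([float(np.trace(_spin_cost(np.asarray(x, float),
                                              np.asarray(s, float), 0,
                                              n_alpha + n_beta)))
                    for s in sites])
    best = int(np.argmin(costs))
    # identity image of any site beating (or tying) every permuted image
    id_best = int(np.argmin(ids))
    if ids[id_best] <= costs[best] + _TIE_TOL:
        return True, id_best
    return False, best


def fold_into_tile(x, sites, n_alpha, n_beta, max_rounds=4):
    """Map x into the tile by relabelling with nearest same-sign images.

    Because Psi^2 is invariant under sign +1 permutations this is measure
    preserving.  Returns (x_folded, owner index, success flag); the repair
    step of the assignment search is not guaranteed optimal, so the fold is
    re-checked and iterated a few rounds.
    """
    y = np.asarray(x, float)
    owner = 0
    for _ in range(max_rounds):
        inside, owner = in_tile(y, sites, n_alpha, n_beta)
        if inside:
            return y, owner, True
        r = nearest_same_sign_image(y, sites[owner], n_alpha, n_beta)
        y = apply_permutation(y, r.permutation)
    inside, owner = in_tile(y, sites, n_alpha, n_beta)
    return y, owner, inside
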