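"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme: Hermite expansion coefficients (E), Hermite
Coulomb integrals (R) built on the Boys function.  One-electron matrices are
assembled in Python over shell pairs with numba-compiled inner tables; the
two-electron repulsion tensor runs fully inside a numba kernel.

Supports s, p and d shells (all that 6-31G(d) needs).  Uses the same basis
convention as :mod:`dvms.wavefunction`: individually normalised Cartesian
components, lexicographic component order, shells in list order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..wavefunction import (
    cartesian_components, primitive_norm, shell_contraction_norm,
    _component_norm_factors,
)

__all__ = [
    "BasisLayout", "overlap", "kinetic", "nuclear_attraction",
    "dipole_matrices", "electron_repulsion",
]

_MAX_L_ENGINE = 2


# --------------------------------------------------------------------------
# numba building blocks
# --------------------------------------------------------------------------

@njit(cache=True)
def _boys(m: int, t: float, out: np.ndarray):
    """Boys functions F_0..F_m at t, written into out[0..m]."""
    if t < 1e-14:
        for n in range(m + 1):
            out[n] = 1.0 / (2 * n + 1)
        return
    if t < 35.0:
        # series at the highest order, then downward recursion
        term = 1.0 / (2 * m + 1)
        s = term
        k = 0
        while term > 1e-17 * s and k < 300:
            k += 1
            term *= 2.0 * t / (2 * m + 2 * k + 1)
            s += term
        emt = math.exp(-t)
        out[m] = emt * s
        for n in range(m - 1, -1, -1):
            out[n] = (2.0 * t * out[n + 1] + emt) / (2 * n + 1)
    else:
        out[0] = 0.5 * math.sqrt(math.pi / t)
        emt = math.exp(-t)
        for n in range(m):
            out[n + 1] = ((2 * n + 1) * out[n] - emt) / (2.0 * t)


@njit(cache=True)
def _e_table(la: int, lb: int, a: float, b: float, q: float, E: np.ndarray):
    """Hermite expansion coefficients E[i, j, t] for a 1D Gaussian pair.

    q = Ax - Bx.  Fills E[0..la, 0..lb, 0..la+lb].
    """
    p = a + b
    mu = a * b / p
    pa = -b * q / p        # Px - Ax
    pb = a * q / p         # Px - Bx
    E[:, :, :] = 0.0
    E[0, 0, 0] = math.exp(-mu * q * q)
    for i in range(la):
        for t in range(i + lb + 2):
            v = pa * E[i, 0, t]
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(la + 1):
        for j in range(lb):
            for t in range(i + j + 2):
                v = pb * E[i, j, t]
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True)
def _r_table(L: int, alpha: float, x: float, y: float, z: float,
             R: np.ndarray, fbuf: np.ndarray):
    """Hermite Coulomb integrals R[n, t, u, v] up to total order L."""
    t2 = alpha * (x * x + y * y + z * z)
    _boys(L, t2, fbuf)
    R[: L + 1, : L + 1, : L + 1, : L + 1] = 0.0
    pw = 1.0
    for n in range(L + 1):
        R[n, 0, 0, 0] = pw * fbuf[n]
        pw *= -2.0 * alpha
    for t in range(1, L + 1):
        for n in range(L - t + 1):
            v = x * R[n + 1, t - 1, 0, 0]
            if t > 1:
                v += (t - 1) * R[n + 1, t - 2, 0, 0]
            R[n, t, 0, 0] = v
    for t in range(L + 1):
        for u in range(1, L - t + 1):
            for n in range(L - t - u + 1):
                v = y * R[n + 1, t, u - 1, 0]
                if u > 1:
                    v += (u - 1) * R[n + 1, t, u - 2, 0]
                R[n, t, u, 0] = v
    for t in range(L + 1):
        for u in range(L - t + 1):
            for v_ in range(1, L - t - u + 1):
                for n in range(L - t - u - v_ + 1):
                    w = z * R[n + 1, t, u, v_ - 1]
                    if v_ > 1:
                        w += (v_ - 1) * R[n + 1, t, u, v_ - 2]
                    R[n, t, u, v_] = w


# --------------------------------------------------------------------------
# basis layout
# --------------------------------------------------------------------------

class BasisLayout:
    """Flat arrays describing a shell list, for the integral kernels.

    Premultiplies contraction coefficients with primitive and contraction
    norms; per-component double-factorial factors are in ``comp_factors``.
    """

    def __init__(self, shells, geometry):
        ns = len(shells)
        self.shells = shells
        self.geometry = geometry
        self.l = np.array([sh.l for sh in shells], dtype=np.int64)
        if np.any(self.l > _MAX_L_ENGINE):
            raise NotImplementedError("integral engine supports l <= 2 (s, p, d)")
        self.centers = np.array([geometry.coords[sh.center] for sh in shells])
        counts = [len(sh.exponents) for sh in shells]
        self.prim_start = np.zeros(ns + 1, dtype=np.int64)
        self.prim_start[1:] = np.cumsum(counts)
        self.exps = np.concatenate([sh.exponents for sh in shells])
        self.coefs = np.concatenate([
            sh.coefficients * primitive_norm(sh.exponents, sh.l)
            * shell_contraction_norm(sh)
            for sh in shells])
        self.ncomp = np.array([sh.n_cartesian for sh in shells], dtype=np.int64)
        self.comp_offset = np.zeros(ns + 1, dtype=np.int64)
        self.comp_offset[1:] = np.cumsum(self.ncomp)
        self.nbf = int(self.comp_offset[-1])
        # component powers / factors packed by l
        self.powers = np.zeros((_MAX_L_ENGINE + 1, 6, 3), dtype=np.int64)
        self.factors = np.zeros((_MAX_L_ENGINE + 1, 6))
        for l in range(_MAX_L_ENGINE + 1):
            comps = cartesian_components(l)
            f = _component_norm_factors(l)
            for ci, (i, j, k) in enumerate(comps):
                self.powers[l, ci] = (i, j, k)
                self.factors[l, ci] = f[ci]


# --------------------------------------------------------------------------
# one-electron matrices
# --------------------------------------------------------------------------

def _pair_tables(lay, A, B, la, lb, a, b, extra=0):
    n = la + lb + 2 * extra + 1
    E = [np.zeros((la + extra + 1, lb + extra + 1, n)) for _ in range(3)]
    for d in range(3):
        _e_table(la + extra, lb + extra, a, b, A[d] - B[d], E[d])
    return E


def overlap(shells, geometry) -> np.ndarray:
    lay = BasisLayout(shells, geometry)
    return _one_electron(lay, kind="overlap")


def kinetic(shells, geometry) -> np.ndarray:
    lay = BasisLayout(shells, geometry)
    return _one_electron(lay, kind="kinetic")


def dipole_matrices(shells, geometry) -> np.ndarray:
    """(3, nbf, nbf) matrices of x, y, z about the origin."""
    lay = BasisLayout(shells, geometry)
    return _one_electron(lay, kind="dipole")


def _one_electron(lay: BasisLayout, kind: str):
    nbf = lay.nbf
    ndim = 3 if kind == "dipole" else 1
    M = np.zeros((ndim, nbf, nbf))
    ns = len(lay.shells)
    for si in range(ns):
        la, A = int(lay.l[si]), lay.centers[si]
        ca = cartesian_components(la)
        fa = lay.factors[la]
        for sj in range(si + 1):
            lb, B = int(lay.l[sj]), lay.centers[sj]
            cb = cartesian_components(lb)
            fb = lay.factors[lb]
            blk = np.zeros((ndim, len(ca), len(cb)))
            for pi in range(lay.prim_start[si], lay.prim_start[si + 1]):
                a, cca = lay.exps[pi], lay.coefs[pi]
                for pj in range(lay.prim_start[sj], lay.prim_start[sj + 1]):
                    b, ccb = lay.exps[pj], lay.coefs[pj]
                    p = a + b
                    pref = cca * ccb * (math.pi / p) ** 1.5
                    E = _pair_tables(lay, A, B, la, lb, a, b, extra=2)
                    for ia, (i1, j1, k1) in enumerate(ca):
                        pw_a = (i1, j1, k1)
                        for ib, (i2, j2, k2) in enumerate(cb):
                            pw_b = (i2, j2, k2)
                            s1d = [E[d][pw_a[d], pw_b[d], 0] for d in range(3)]
                            if kind == "overlap":
                                blk[0, ia, ib] += pref * s1d[0] * s1d[1] * s1d[2]
                            elif kind == "kinetic":
                                tt = 0.0
                                for d in range(3):
                                    jj = pw_b[d]
                                    kin = -2.0 * b * b * E[d][pw_a[d], jj + 2, 0] \
                                        + b * (2 * jj + 1) * E[d][pw_a[d], jj, 0]
                                    if jj >= 2:
                                        kin -= 0.5 * jj * (jj - 1) * E[d][pw_a[d], jj - 2, 0]
                                    term = kin
                                    for dd in range(3):
                                        if dd != d:
                                            term *= s1d[dd]
                                    tt += term
                                blk[0, ia, ib] += pref * tt
                            else:  # dipole
                                for d in range(3):
                                    m1d = E[d][pw_a[d] + 1, pw_b[d], 0] \
                                        + A[d] * E[d][pw_a[d], pw_b[d], 0]
                                    term = m1d
                                    for dd in range(3):
                                        if dd != d:
                                            term *= s1d[dd]
                                    blk[d, ia, ib] += pref * term
            blk *= fa[: len(ca), None] * fb[None, : len(cb)]
            oi, oj = lay.comp_offset[si], lay.comp_offset[sj]
            M[:, oi:oi + len(ca), oj:oj + len(cb)] = blk
            M[:, oj:oj + len(cb), oi:oi + len(ca)] = np.transpose(blk, (0, 2, 1))
    return M[0] if ndim == 1 else M


def nuclear_attraction(shells, geometry) -> np.ndarray:
    lay = BasisLayout(shells, geometry)
    nbf = lay.nbf
    V = np.zeros((nbf, nbf))
    ns = len(lay.shells)
    Rbuf = np.zeros((6, 6, 6, 6))
    fbuf = np.zeros(16)
    Z = geometry.numbers.astype(float)
    for si in range(ns):
        la, A = int(lay.l[si]), lay.centers[si]
        ca = cartesian_components(la)
        fa = lay.factors[la]
        for sj in range(si + 1):
            lb, B = int(lay.l[sj]), lay.centers[sj]
            cb = cartesian_components(lb)
            fb = lay.factors[lb]
            L = la + lb
            blk = np.zeros((len(ca), len(cb)))
            for pi in range(lay.prim_start[si], lay.prim_start[si + 1]):
                a, cca = lay.exps[pi], lay.coefs[pi]
                for pj in range(lay.prim_start[sj], lay.prim_start[sj + 1]):
                    b, ccb = lay.exps[pj], lay.coefs[pj]
                    p = a + b
                    P = (a * A + b * B) / p
                    E = _pair_tables(lay, A, B, la, lb, a, b)
                    pref = cca * ccb * 2.0 * math.pi / p
                    for iat in range(len(Z)):
                        C = geometry.coords[iat]
                        _r_table(L, p, P[0] - C[0], P[1] - C[1], P[2] - C[2],
                                 Rbuf, fbuf)
                        for ia, (i1, j1, k1) in enumerate(ca):
                            for ib, (i2, j2, k2) in enumerate(cb):
                                s = 0.0
                                for t in range(i1 + i2 + 1):
                                    ex = E[0][i1, i2, t]
                                    for u in range(j1 + j2 + 1):
                                        ey = E[1][j1, j2, u]
                                        for v in range(k1 + k2 + 1):
                                            s += ex * ey * E[2][k1, k2, v] \
                                                * Rbuf[0, t, u, v]
                                blk[ia, ib] -= Z[iat] * pref * s
            blk *= fa[: len(ca), None] * fb[None, : len(cb)]
            oi, oj = lay.comp_offset[si], lay.comp_offset[sj]
            V[oi:oi + len(ca), oj:oj + len(cb)] = blk
            V[oj:oj + len(cb), oi:oi + len(ca)] = blk.T
    return V


# --------------------------------------------------------------------------
# two-electron repulsion tensor
# --------------------------------------------------------------------------

@njit(cache=True)
def _eri_kernel(l_arr, centers, prim_start, exps, coefs, comp_offset,
                powers, factors, eri):
    ns = len(l_arr)
    Emax = 3
    Ea = np.zeros((3, Emax, Emax, 2 * Emax - 1))
    Ec = np.zeros((3, Emax, Emax, 2 * Emax - 1))
    Rbuf = np.zeros((9, 9, 9, 9))
    fbuf = np.zeros(16)
    J = np.zeros((5, 5, 5, 36))
    for si in range(ns):
        la = l_arr[si]
        na = (la + 1) * (la + 2) // 2
        A = centers[si]
        for sj in range(si + 1):
            lb = l_arr[sj]
            nb = (lb + 1) * (lb + 2) // 2
            B = centers[sj]
            pair_ij = si * (si + 1) // 2 + sj
            for sk in range(ns):
                lc = l_arr[sk]
                ncc = (lc + 1) * (lc + 2) // 2
                C = centers[sk]
                for sl in range(sk + 1):
                    pair_kl = sk * (sk + 1) // 2 + sl
                    if pair_kl > pair_ij:
                        continue
                    ld = l_arr[sl]
                    nd = (ld + 1) * (ld + 2) // 2
                    D = centers[sl]
                    L = la + lb + lc + ld
                    block = np.zeros((na, nb, ncc, nd))
                    for pi in range(prim_start[si], prim_start[si + 1]):
                        a = exps[pi]
                        for pj in range(prim_start[sj], prim_start[sj + 1]):
                            b = exps[pj]
                            p = a + b
                            Px = (a * A[0] + b * B[0]) / p
                            Py = (a * A[1] + b * B[1]) / p
                            Pz = (a * A[2] + b * B[2]) / p
                            for d in range(3):
                                _e_table(la, lb, a, b, A[d] - B[d], Ea[d])
                            cab = coefs[pi] * coefs[pj]
                            for pk in range(prim_start[sk], prim_start[sk + 1]):
                                c = exps[pk]
                                for pl in range(prim_start[sl], prim_start[sl + 1]):
                                    dd = exps[pl]
                                    q = c + dd
                                    Qx = (c * C[0] + dd * D[0]) / q
                                    Qy = (c * C[1] + dd * D[1]) / q
                                    Qz = (c * C[2] + dd * D[2]) / q
                                    for d in range(3):
                                        _e_table(lc, ld, c, dd, C[d] - D[d], Ec[d])
                                    alpha = p * q / (p + q)
                                    _r_table(L, alpha, Px - Qx, Py - Qy,
                                             Pz - Qz, Rbuf, fbuf)
                                    pref = (cab * coefs[pk] * coefs[pl]
                                            * 2.0 * math.pi ** 2.5
                                            / (p * q * math.sqrt(p + q)))
                                    # J[t,u,v, cd-pair] = sum over cd Hermite
                                    nab1 = la + lb + 1
                                    for t in range(nab1):
                                        for u in range(nab1 - t):
                                            for v in range(nab1 - t - u):
                                                for ccd in range(ncc * nd):
                                                    J[t, u, v, ccd] = 0.0
                                    for ic in range(ncc):
                                        i3 = powers[lc, ic, 0]
                                        j3 = powers[lc, ic, 1]
                                        k3 = powers[lc, ic, 2]
                                        for idd in range(nd):
                                            i4 = powers[ld, idd, 0]
                                            j4 = powers[ld, idd, 1]
                                            k4 = powers[ld, idd, 2]
                                            ccd = ic * nd + idd
                                            for t in range(la + lb + 1):
                                                for u in range(la + lb + 1 - t):
                                                    for v in range(la + lb + 1 - t - u):
                                                        s = 0.0
                                                        for tau in range(i3 + i4 + 1):
                                                            ex = Ec[0][i3, i4, tau]
                                                            if ex == 0.0:
                                                                continue
                                                            for nu in range(j3 + j4 + 1):
                                                                ey = Ec[1][j3, j4, nu]
                                                                if ey == 0.0:
                                                                    continue
                                                                for ph in range(k3 + k4 + 1):
                                                                    ez = Ec[2][k3, k4, ph]
                                                                    if ez == 0.0:
                                                                        continue
                                                                    sgn = 1.0 if (tau + nu + ph) % 2 == 0 else -1.0
                                                                    s += sgn * ex * ey * ez * Rbuf[0, t + tau, u + nu, v + ph]
                                                        J[t, u, v, ccd] = s
                                    for ia in range(na):
                                        i1 = powers[la, ia, 0]
                                        j1 = powers[la, ia, 1]
                                        k1 = powers[la, ia, 2]
                                        for ib in range(nb):
                                            i2 = powers[lb, ib, 0]
                                            j2 = powers[lb, ib, 1]
                                            k2 = powers[lb, ib, 2]
                                            for ic in range(ncc):
                                                for idd in range(nd):
                                                    ccd = ic * nd + idd
                                                    s = 0.0
                                                    for t in range(i1 + i2 + 1):
                                                        ex = Ea[0][i1, i2, t]
                                                        if ex == 0.0:
                                                            continue
                                                        for u in range(j1 + j2 + 1):
                                                            ey = Ea[1][j1, j2, u]
                                                            if ey == 0.0:
                                                                continue
                                                            for v in range(k1 + k2 + 1):
                                                                s += ex * ey * Ea[2][k1, k2, v] * J[t, u, v, ccd]
                                                    block[ia, ib, ic, idd] += pref * s
                    # scatter with normalisation factors and 8-fold symmetry
                    oi = comp_offset[si]
                    oj = comp_offset[sj]
                    ok = comp_offset[sk]
                    ol = comp_offset[sl]
                    for ia in range(na):
                        fa = factors[la, ia]
                        for ib in range(nb):
                            fb = factors[lb, ib]
                            for ic in range(ncc):
                                fc = factors[lc, ic]
                                for idd in range(nd):
                                    val = block[ia, ib, ic, idd] * fa * fb \
                                        * fc * factors[ld, idd]
                                    mu, nu_, lam, sg = oi + ia, oj + ib, ok + ic, ol + idd
                                    eri[mu, nu_, lam, sg] = val
                                    eri[nu_, mu, lam, sg] = val
                                    eri[mu, nu_, sg, lam] = val
                                    eri[nu_, mu, sg, lam] = val
                                    eri[lam, sg, mu, nu_] = val
                                    eri[sg, lam, mu, nu_] = val
                                    eri[lam, sg, nu_, mu] = val
                                    eri[sg, lam, nu_, mu] = val


def electron_repulsion(shells, geometry) -> np.ndarray:
    """Full (nbf, nbf, nbf, nbf) two-electron repulsion tensor in chemists'
    notation (mu nu | lam sg)."""
    lay = BasisLayout(shells, geometry)
    eri = np.zeros((lay.nbf,) * 4)
    _eri_kernel(lay.l, lay.centers, lay.prim_start, lay.exps, lay.coefs,
                lay.comp_offset, lay.powers, lay.factors, eri)
    return eri
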