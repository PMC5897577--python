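"""Small complete-active-space CI and Slater-Condon matrix elements.

Full CI in a tiny active space over canonical Hartree-Fock orbitals, used to
generate the few-configuration wavefunctions that capture homolytic bond
cleavage.  Determinant Hamiltonian and one-particle density matrices follow
the Slater-Condon rules over orthonormal orbitals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["casci_ground_state", "one_particle_rdm"]


def _excitation(occ1, occ2):
    """(holes, particles, sign) taking occ1 to occ2, or None if >2 diffs.

    Sign is the permutation phase of aligning the two ordered occupation
    lists after the excitation.
    """
    s1, s2 = set(occ1), set(occ2)
    holes = sorted(s1 - s2)
    parts = sorted(s2 - s1)
    if len(holes) > 2:
        return None
    # phase: count transpositions to move each hole to its particle slot
    perm = list(occ1)
    sign = 1
    for h, p in zip(holes, parts):
        i = perm.index(h)
        perm[i] = p
    # sort perm recording parity
    arr = list(perm)
    for i in range(len(arr)):
        j = min(range(i, len(arr)), key=arr.__getitem__)
        if j != i:
            arr[i], arr[j] = arr[j], arr[i]
            sign = -sign
    return holes, parts, sign


def _h_element(det1, det2, h, eri):
    """<det1|H|det2> with dets = (alpha tuple, beta tuple), integrals in MO
    basis, eri in chemists' notation (ij|kl)."""
    ea = _excitation(det1[0], det2[0])
    eb = _excitation(det1[1], det2[1])
    if ea is None or eb is None:
        return 0.0
    na_diff, nb_diff = len(ea[0]), len(eb[0])
    if na_diff + nb_diff > 2:
        return 0.0
    a1, b1 = det1
    if na_diff == 0 and nb_diff == 0:
        e = sum(h[i, i] for i in a1) + sum(h[i, i] for i in b1)
        for occ in (a1, b1):
            for i in occ:
                for j in occ:
                    e += 0.5 * (eri[i, i, j, j] - eri[i, j, j, i])
        for i in a1:
            for j in b1:
                e += eri[i, i, j, j]
        return e
    if na_diff + nb_diff == 1:
        if na_diff == 1:
            (m,), (p,), sign = ea
            same, other = a1, b1
        else:
            (m,), (p,), sign = eb
            same, other = b1, a1
        e = h[m, p]
        for n in same:
            if n != m:
                e += eri[m, p, n, n] - eri[m, n, n, p]
        for n in other:
            e += eri[m, p, n, n]
        return sign * e
    # double excitation
    if na_diff == 2:
        (m, n), (p, q), sign = ea
        return sign * (eri[m, p, n, q] - eri[m, q, n, p])
    if nb_diff == 2:
        (m, n), (p, q), sign = eb
        return sign * (eri[m, p, n, q] - eri[m, q, n, p])
    (m,), (p,), sa = ea
    (n,), (q,), sb = eb
    return sa * sb * eri[m, p, n, q]


def one_particle_rdm(determinants, coefficients, n_orbitals) -> np.ndarray:
    """Spin-summed one-particle density matrix gamma_pq = <a+_p a_q>.

    ``determinants``: list of (alpha tuple, beta tuple) over orbital indices
    < n_orbitals; ``coefficients`` the normalised CI vector.
    """
    gamma = np.zeros((n_orbitals, n_orbitals))
    c = np.asarray(coefficients, float)
    for I, dI in enumerate(determinants):
        for J, dJ in enumerate(determinants):
            ea = _excitation(dI[0], dJ[0])
            eb = _excitation(dI[1], dJ[1])
            if ea is None or eb is None:
                continue
            nda, ndb = len(ea[0]), len(eb[0])
            if nda + ndb > 1:
                continue
            w = c[I] * c[J]
            if nda == 0 and ndb == 0:
                for i in dI[0]:
                    gamma[i, i] += w
                for i in dI[1]:
                    gamma[i, i] += w
            elif nda == 1:
                (m,), (p,), sign = ea
                gamma[m, p] += sign * w
            else:
                (m,), (p,), sign = eb
                gamma[m, p] += sign * w
    return gamma


def casci_ground_state(h_act, eri_act, n_alpha_act, n_beta_act):
    """Ground state of the active-space Hamiltonian.

    Returns (energy_active, determinant list over active indices, CI vector).
    """
    norb = h_act.shape[0]
    dets_a = list(combinations(range(norb), n_alpha_act))
    dets_b = list(combinations(range(norb), n_beta_act))
    dets = [(a, b) for a in dets_a for b in dets_b]
    n = len(dets)
    if n > 4000:
        raise ValueError(f"active space too large ({n} determinants)")
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            H[i, j] = H[j, i] = _h_element(dets[i], dets[j], h_act, eri_act)
    w, v = np.linalg.eigh(H)
    return w[0], dets, v[:, 0]
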