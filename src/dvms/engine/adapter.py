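"""Engine adapter: turn geometries into CIWavefunction objects.

Wraps the internal RHF/UHF + CASCI engine behind the interface the rest of
the package consumes: a geometry, a basis name and a configuration count in;
a normalised multi-determinant wavefunction out.  "Excited" configurations
are the largest-|coefficient| determinants of a small complete-active-space
CI around the frontier orbitals, truncated and renormalised.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from ..units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from ..wavefunction import CIWavefunction, Determinant, Geometry
from . import integrals
from .basis_data import build_shells
from .casci import casci_ground_state, one_particle_rdm
from .scf import run_rhf, run_uhf

__all__ = [
    "build_wavefunction", "optimize_diatomic_bond_length",
    "expectation_dipole", "orbital_orthonormality_error",
]


def build_wavefunction(geometry: Geometry, basis_name="6-31g(d)",
                       n_configs=1, method="auto",
                       active_space=None, active_orbitals=None) -> CIWavefunction:
    """Hartree-Fock (+ optional small CASCI) wavefunction for a geometry.

    ``n_configs`` determinants are kept: 1 reproduces the single-determinant
    reference; more keeps the leading CASCI determinants (renormalised).
    ``active_space``: (n_electrons, n_orbitals), default (2, 2) around the
    frontier orbitals; ``active_orbitals`` overrides the orbital window with
    explicit MO indices (e.g. a sigma/sigma* pair that is not the
    HOMO/LUMO).
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    if method == "auto":
        method = "rhf" if geometry.multiplicity == 1 else "uhf"
    if method == "uhf":
        if n_configs != 1:
            raise NotImplementedError("multi-configuration UHF not supported")
        res = run_uhf(geometry, basis_name)
        nmo = res.mo_coefficients.shape[1]
        C = np.hstack([res.mo_coefficients, res.mo_coefficients_beta])
        det = Determinant(tuple(range(res.n_alpha)),
                          tuple(nmo + i for i in range(res.n_beta)))
        return CIWavefunction(
            geometry, res.shells, C, [det], np.array([1.0]),
            res.n_alpha, res.n_beta,
            meta={"method": "uhf", "basis": basis_name,
                  "scf_energy": res.energy, "n_configs": 1})
    res = run_rhf(geometry, basis_name)
    nocc = res.n_alpha
    if n_configs == 1:
        det = Determinant(tuple(range(nocc)), tuple(range(nocc)))
        return CIWavefunction(
            geometry, res.shells, res.mo_coefficients, [det], np.array([1.0]),
            res.n_alpha, res.n_beta,
            meta={"method": "rhf", "basis": basis_name,
                  "scf_energy": res.energy, "n_configs": 1})
    # small CASCI around the frontier orbitals (or explicit window)
    if active_orbitals is not None:
        act = sorted(int(i) for i in active_orbitals)
    else:
        nel_act, norb_act = active_space if active_space else (2, 2)
        act = list(range(nocc - nel_act // 2,
                         nocc - nel_act // 2 + norb_act))
    return casci_wavefunction(geometry, res.shells, res.mo_coefficients,
                              nocc, act, n_configs,
                              basis_name=basis_name, scf_energy=res.energy)


def casci_wavefunction(geometry, shells, C, nocc, active_orbitals, n_configs,
                       basis_name="6-31g(d)", scf_energy=None,
                       nroot=0) -> CIWavefunction:
    """Full CI in an explicit active-orbital window over given orbitals.

    Doubly occupies all occupied orbitals outside the window, solves the
    active-space Hamiltonian exactly, keeps the ``n_configs``
    largest-|coefficient| determinants and renormalises.
    """
    act = sorted(int(i) for i in active_orbitals)
    nel_act = 2 * sum(1 for i in act if i < nocc)
    ncore_orbs = [i for i in range(nocc) if i not in act]
    if nel_act < 1 or any(i < 0 for i in act):
        raise ValueError("invalid active space")
    H1 = (integrals.kinetic(shells, geometry)
          + integrals.nuclear_attraction(shells, geometry))
    eri = integrals.electron_repulsion(shells, geometry)
    Dcore = 2.0 * C[:, ncore_orbs] @ C[:, ncore_orbs].T
    J = np.einsum("pqrs,rs->pq", eri, Dcore, optimize=True)
    K = np.einsum("prqs,rs->pq", eri, Dcore, optimize=True)
    h_eff = H1 + J - 0.5 * K
    Cact = C[:, act]
    h_act = Cact.T @ h_eff @ Cact
    eri_act = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri, Cact, Cact, Cact, Cact,
                        optimize=True)
    e_act, dets_act, ci = casci_ground_state(h_act, eri_act,
                                             nel_act // 2, nel_act // 2)
    e_core = 0.5 * np.sum(Dcore * (H1 + h_eff)) + geometry.nuclear_repulsion()
    order = np.argsort(-np.abs(ci))[:n_configs]
    kept = np.array(sorted(order))
    coeffs = ci[kept]
    coeffs = coeffs / np.linalg.norm(coeffs)

    def _merge(occ_act):
        """Sort (core + active) occupation; the parity of the sort matters
        for the determinant's sign convention."""
        arr = list(ncore_orbs) + [act[i] for i in occ_act]
        sign = 1
        for i in range(len(arr)):            # selection sort, counting swaps
            j = min(range(i, len(arr)), key=arr.__getitem__)
            if j != i:
                arr[i], arr[j] = arr[j], arr[i]
                sign = -sign
        return tuple(arr), sign

    dets = []
    for ki, idx in enumerate(kept):
        da, db = dets_act[idx]
        occ_a, sgn_a = _merge(da)
        occ_b, sgn_b = _merge(db)
        coeffs[ki] *= sgn_a * sgn_b
        dets.append(Determinant(occ_a, occ_b))
    na = nb = nocc
    return CIWavefunction(
        geometry, shells, C, dets, coeffs, na, nb,
        meta={"method": f"casci({nel_act},{len(act)})", "basis": basis_name,
              "scf_energy": scf_energy, "casci_energy": e_core + e_act,
              "n_configs": int(n_configs),
              "full_ci_dim": len(dets_act)})


def optimize_diatomic_bond_length(symbols, basis_name="6-31g(d)",
                                  bounds_angstrom=(0.6, 1.6),
                                  charge=0, tol=1e-5):
    """Equilibrium bond length (Angstrom) of a diatomic at the restricted
    reference level, by scalar minimisation of the RHF energy."""

    def energy(r_angstrom):
        geom = Geometry.from_angstrom(
            symbols, [[0.0, 0.0, 0.0], [0.0, 0.0, r_angstrom]], charge=charge)
        return run_rhf(geom, basis_name).energy

    res = minimize_scalar(energy, bounds=bounds_angstrom, method="bounded",
                          options={"xatol": tol})
    if not res.success:
        raise RuntimeError("bond-length optimisation failed")
    return float(res.x), float(res.fun)


def expectation_dipole(wf: CIWavefunction) -> np.ndarray:
    """<Psi| mu |Psi> in atomic units, mu = sum_A Z_A R_A - sum_p r_p.

    Uses the Slater-Condon one-particle density matrix, so it is exact for
    any determinant expansion over orthonormal orbitals.
    """
    nmo = wf.mo_coefficients.shape[1]
    dets = [(d.alpha, d.beta) for d in wf.determinants]
    gamma = one_particle_rdm(dets, wf.ci_coefficients, nmo)
    D_ao = wf.mo_coefficients @ gamma @ wf.mo_coefficients.T
    mu_ints = integrals.dipole_matrices(wf.shells, wf.geometry)
    elec = np.array([np.sum(D_ao * mu_ints[d]) for d in range(3)])
    nuc = (wf.geometry.numbers[:, None] * wf.geometry.coords).sum(axis=0)
    return nuc - elec


def orbital_orthonormality_error(wf: CIWavefunction) -> float:
    """Max deviation of occupied-orbital overlaps from the identity."""
    S = integrals.overlap(wf.shells, wf.geometry)
    occ = sorted({i for d in wf.determinants for i in d.alpha + d.beta})
    C = wf.mo_coefficients[:, occ]
    return float(np.max(np.abs(C.T @ S @ C - np.eye(len(occ)))))
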