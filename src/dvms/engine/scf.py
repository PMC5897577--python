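"""Restricted and unrestricted Hartree-Fock for small molecules.

A deliberately compact SCF: core-Hamiltonian guess, DIIS acceleration,
dense in-memory two-electron tensor.  Adequate for the few-heavy-atom
systems this package samples; not a general-purpose quantum-chemistry code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import integrals
from .basis_data import build_shells

__all__ = ["SCFResult", "run_rhf", "run_uhf", "SCFError"]


class SCFError(RuntimeError):
    """Self-consistent field failed to converge."""


@dataclass
class SCFResult:
    energy: float
    mo_coefficients: np.ndarray      # restricted: (nbf, nmo); UHF: per spin
    mo_energies: np.ndarray
    mo_coefficients_beta: np.ndarray | None
    mo_energies_beta: np.ndarray | None
    n_alpha: int
    n_beta: int
    shells: list
    geometry: object
    converged: bool
    n_iterations: int

    @property
    def restricted(self) -> bool:
        return self.mo_coefficients_beta is None


def _spin_counts(geometry):
    n = geometry.n_electrons
    mult = geometry.multiplicity
    n_unpaired = mult - 1
    if (n - n_unpaired) % 2:
        raise ValueError("electron count and multiplicity are inconsistent")
    nb = (n - n_unpaired) // 2
    return nb + n_unpaired, nb


def _core_pieces(shells, geometry):
    S = integrals.overlap(shells, geometry)
    T = integrals.kinetic(shells, geometry)
    V = integrals.nuclear_attraction(shells, geometry)
    eri = integrals.electron_repulsion(shells, geometry)
    w, U = np.linalg.eigh(S)
    if w.min() < 1e-8:
        raise SCFError("near-singular overlap matrix")
    X = U @ np.diag(w ** -0.5) @ U.T
    return S, T + V, eri, X


class _DIIS:
    def __init__(self, size=8):
        self.f, self.e = [], []
        self.size = size

    def extrapolate(self, F, err):
        self.f.append(F.copy())
        self.e.append(err.ravel().copy())
        if len(self.f) > self.size:
            self.f.pop(0), self.e.pop(0)
        n = len(self.f)
        if n < 2:
            return F
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.e[i] @ self.e[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            self.f, self.e = [self.f[-1]], [self.e[-1]]
            return F
        return sum(ci * Fi for ci, Fi in zip(c, self.f))


def run_rhf(geometry, basis_name="6-31g(d)", shells=None, max_iter=200,
            conv=1e-9) -> SCFResult:
    """Closed-shell restricted Hartree-Fock."""
    na, nb = _spin_counts(geometry)
    if na != nb:
        raise ValueError("RHF needs a closed-shell geometry (multiplicity 1)")
    shells = shells if shells is not None else build_shells(geometry, basis_name)
    S, H, eri, X = _core_pieces(shells, geometry)
    enuc = geometry.nuclear_repulsion()
    nocc = na
    F = H
    diis = _DIIS()
    e_old, D = 0.0, None
    for it in range(1, max_iter + 1):
        eps, Cp = np.linalg.eigh(X.T @ F @ X)
        C = X @ Cp
        D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        F = H + J - 0.5 * K
        e = 0.5 * np.sum(D * (H + F)) + enuc
        err = F @ D @ S - S @ D @ F
        if abs(e - e_old) < conv and np.max(np.abs(err)) < 1e-5:
            return SCFResult(e, C, eps, None, None, na, nb, shells, geometry,
                             True, it)
        e_old = e
        F = diis.extrapolate(F, X.T @ err @ X)
    raise SCFError(f"RHF did not converge in {max_iter} iterations "
                   f"(last energy {e_old:.8f})")


def run_uhf(geometry, basis_name="6-31g(d)", shells=None, max_iter=300,
            conv=1e-9) -> SCFResult:
    """Unrestricted Hartree-Fock (open shells)."""
    na, nb = _spin_counts(geometry)
    shells = shells if shells is not None else build_shells(geometry, basis_name)
    S, H, eri, X = _core_pieces(shells, geometry)
    enuc = geometry.nuclear_repulsion()
    Fa = Fb = H
    diis_a, diis_b = _DIIS(), _DIIS()
    e_old = 0.0
    for it in range(1, max_iter + 1):
        epsa, Cpa = np.linalg.eigh(X.T @ Fa @ X)
        epsb, Cpb = np.linalg.eigh(X.T @ Fb @ X)
        Ca, Cb = X @ Cpa, X @ Cpb
        Da = Ca[:, :na] @ Ca[:, :na].T
        Db = Cb[:, :nb] @ Cb[:, :nb].T
        Dt = Da + Db
        J = np.einsum("pqrs,rs->pq", eri, Dt, optimize=True)
        Ka = np.einsum("prqs,rs->pq", eri, Da, optimize=True)
        Kb = np.einsum("prqs,rs->pq", eri, Db, optimize=True)
        Fa = H + J - Ka
        Fb = H + J - Kb
        e = 0.5 * (np.sum(Dt * H) + np.sum(Da * Fa) + np.sum(Db * Fb)) + enuc
        erra = Fa @ Da @ S - S @ Da @ Fa
        errb = Fb @ Db @ S - S @ Db @ Fb
        emax = max(np.max(np.abs(erra)), np.max(np.abs(errb)))
        if abs(e - e_old) < conv and emax < 1e-5:
            return SCFResult(e, Ca, epsa, Cb, epsb, na, nb, shells, geometry,
                             True, it)
        e_old = e
        Fa = diis_a.extrapolate(Fa, X.T @ erra @ X)
        Fb = diis_b.extrapolate(Fb, X.T @ errb @ X)
    raise SCFError(f"UHF did not converge in {max_iter} iterations "
                   f"(last energy {e_old:.8f})")
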