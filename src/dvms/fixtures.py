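"""Wavefunction fixtures: analytic toys with known tiles, and real
molecular wavefunctions from the built-in Hartree-Fock/CASCI engine.

The toys make the whole sampling stack testable without any electronic
structure: displaced-Gaussian determinants have analytically known tile
centroids (the generating centers, once the centers are well separated),
and the two-configuration H2 model has a closed-form amplitude.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import build_wavefunction, run_rhf
from .engine.integrals import overlap
from .units import BOHR_PER_ANGSTROM
from .wavefunction import BasisShell, CIWavefunction, Determinant, Geometry

__all__ = [
    "make_toy_determinant", "make_h2_two_config", "build_from_engine",
    "h2_two_config_amplitude", "demo_geometry", "packaged_fixture",
    "hf_molecule_two_config", "bond_electron_feature",
]


def packaged_fixture(name):
    """Load one of the containers shipped with the package.

    Available: water_rhf_631gd, methyl_uhf_631gd, hf_2cfg_0.91 / 1.01 /
    1.11 / 1.31 / 1.51.
    """
    from importlib.resources import files
    from .io import load_wavefunction
    path = files("dvms.data") / f"{name}.json"
    if not path.is_file():
        raise FileNotFoundError(f"no packaged fixture {name!r}")
    return load_wavefunction(str(path))


def make_toy_determinant(centers, width=1.0, spins=None) -> CIWavefunction:
    """Single determinant of displaced s-Gaussians, one electron each.

    ``centers``: (n, 3) bohr; ``width``: Gaussian sigma in bohr (orbital
    exp(-|r-c|^2 / (2 width^2))); ``spins``: sequence of "a"/"b" (default
    all alpha).  Orbitals are symmetrically (Lowdin) orthogonalised, which
    leaves them center-localised for separations >~ 6 width.  For such
    separations the tile's Voronoi site converges to the centers.
    """
    centers = np.asarray(centers, float).reshape(-1, 3)
    n = len(centers)
    if n < 1 or width <= 0:
        raise ValueError("need >= 1 center and positive width")
    spins = ["a"] * n if spins is None else list(spins)
    if len(spins) != n or any(s not in ("a", "b") for s in spins):
        raise ValueError("spins must be 'a'/'b', one per center")
    # same-spin duplicate centers give a singular determinant
    for i in range(n):
        for j in range(i):
            if spins[i] == spins[j] and \
                    np.linalg.norm(centers[i] - centers[j]) < 1e-9:
                raise ValueError("duplicate center with the same spin "
                                 "(degenerate orbitals)")
    order = [i for i in range(n) if spins[i] == "a"] + \
            [i for i in range(n) if spins[i] == "b"]
    centers = centers[order]
    n_alpha = sum(1 for s in spins if s == "a")
    n_beta = n - n_alpha
    # deduplicate coincident centers (legal across spins) so the overlap
    # stays regular; each electron occupies its center's orbital
    unique, orb_of = [], []
    for c in centers:
        for k, u in enumerate(unique):
            if np.linalg.norm(c - u) < 1e-9:
                orb_of.append(k)
                break
        else:
            orb_of.append(len(unique))
            unique.append(c)
    unique = np.asarray(unique)
    # order electrons within each spin block by orbital index so the
    # determinant occupation lists are strictly increasing
    ia = sorted(range(n_alpha), key=lambda i: orb_of[i])
    ib = sorted(range(n_alpha, n), key=lambda i: orb_of[i])
    centers = centers[ia + ib]
    orb_of = [orb_of[i] for i in ia + ib]
    geom = Geometry(["H"] * n, centers, charge=0,
                    multiplicity=1 + abs(n_alpha - n_beta))
    a = 1.0 / (2.0 * width ** 2)
    # shells sit on the (possibly duplicated) electron centers but only one
    # per unique position
    first_atom_of = [int(np.where(np.linalg.norm(centers - u, axis=1)
                                  < 1e-9)[0][0]) for u in unique]
    shells = [BasisShell(iatom, 0, [a], [1.0]) for iatom in first_atom_of]
    S = overlap(shells, geom)
    w, U = np.linalg.eigh(S)
    C = U @ np.diag(w ** -0.5) @ U.T          # Lowdin orthogonalisation
    det = Determinant(tuple(orb_of[:n_alpha]),
                      tuple(orb_of[n_alpha:]))
    return CIWavefunction(geom, shells, C, [det], np.array([1.0]),
                          n_alpha, n_beta,
                          meta={"kind": "toy_determinant", "width": width})


def make_h2_two_config(r_angstrom, c_g, c_u, exponent=0.5) -> CIWavefunction:
    """Two-configuration H2: c_g |sigma_g^2| + c_u |sigma_u^2|.

    Minimal basis of one s Gaussian per nucleus (``exponent`` in bohr^-2);
    sigma_g/u = (a +/- b)/sqrt(2 (1 +/- S)).  With c_u < 0 the ionic terms
    are suppressed, the Coulson-Fischer picture of homolytic cleavage.
    """
    if r_angstrom <= 0:
        raise ValueError("bond length must be positive")
    if abs(c_g ** 2 + c_u ** 2 - 1.0) > 1e-8:
        raise ValueError("configuration coefficients must satisfy "
                         "c_g^2 + c_u^2 = 1")
    r = r_angstrom * BOHR_PER_ANGSTROM
    geom = Geometry(["H", "H"], [[0, 0, -r / 2], [0, 0, r / 2]])
    shells = [BasisShell(0, 0, [exponent], [1.0]),
              BasisShell(1, 0, [exponent], [1.0])]
    S = overlap(shells, geom)
    s01 = S[0, 1]
    ng = 1.0 / math.sqrt(2.0 * (1.0 + s01))
    nu = 1.0 / math.sqrt(2.0 * (1.0 - s01))
    C = np.array([[ng, nu], [ng, -nu]])
    dets = [Determinant((0,), (0,)), Determinant((1,), (1,))]
    coeffs = np.array([c_g, c_u], float)
    if abs(c_u) < 1e-15:
        dets, coeffs = dets[:1], np.array([1.0])
    return CIWavefunction(geom, shells, C, dets, coeffs, 1, 1,
                          meta={"kind": "h2_two_config", "R": r_angstrom,
                                "c_g": c_g, "c_u": c_u,
                                "exponent": exponent})


def h2_two_config_amplitude(wf: CIWavefunction, r1, r2) -> float:
    """Closed-form oracle for :func:`make_h2_two_config`.

    Psi(r1, r2) = c_g sg(r1) sg(r2) + c_u su(r1) su(r2) with sg/su the
    normalised symmetric/antisymmetric combinations of the two atomic
    s Gaussians; independent of the production determinant path.
    """
    a = wf.meta["exponent"]
    R = wf.geometry.coords
    s01 = overlap(wf.shells, wf.geometry)[0, 1]
    norm = (2.0 * a / math.pi) ** 0.75

    def ao(r):
        return np.array([norm * math.exp(-a * np.sum((np.asarray(r) - R[i]) ** 2))
                         for i in range(2)])

    ng = 1.0 / math.sqrt(2.0 * (1.0 + s01))
    nu = 1.0 / math.sqrt(2.0 * (1.0 - s01))
    a1, a2 = ao(r1), ao(r2)
    sg = lambda v: ng * (v[0] + v[1])
    su = lambda v: nu * (v[0] - v[1])
    c_g, c_u = wf.meta["c_g"], wf.meta["c_u"]
    return c_g * sg(a1) * sg(a2) + c_u * su(a1) * su(a2)


def build_from_engine(geometry: Geometry, basis_name="6-31g(d)", n_configs=1,
                      method="auto", active_space=None,
                      active_orbitals=None) -> CIWavefunction:
    """Engine-backed wavefunction (reference + leading CASCI excitations)."""
    return build_wavefunction(geometry, basis_name, n_configs, method,
                              active_space, active_orbitals)


def hf_molecule_two_config(r_angstrom=0.91, basis_name="6-31g(d)",
                           n_configs=2) -> CIWavefunction:
    """Hydrogen fluoride with the sigma/sigma* correlation pair active.

    The HOMO of HF is a fluorine lone-pair pi orbital; homolytic cleavage
    correlation lives in the sigma bond instead, so the active pair is
    picked by hydrogen s-character: the occupied and lowest virtual MOs
    with the largest |coefficient| on the H atom's s functions.
    """
    geom = demo_geometry("hf", r=r_angstrom)
    res = run_rhf(geom, basis_name)
    C = res.mo_coefficients
    # indices of H s basis functions
    from .wavefunction import cartesian_components
    idx, pos = [], 0
    for sh in res.shells:
        ncomp = sh.n_cartesian
        if geom.symbols[sh.center] == "H" and sh.l == 0:
            idx.extend(range(pos, pos + ncomp))
        pos += ncomp
    h_char = np.abs(C[idx]).sum(axis=0)
    nocc = res.n_alpha
    sigma = int(np.argmax(h_char[:nocc]))
    # Iterated natural-orbital pair CI: CI of the sigma pair over the full
    # virtual space, then replace {sigma, sigma*} by the natural orbitals
    # of the pair density and repeat.  This approximates a two-configuration
    # SCF: raw RHF orbitals spread the pair correlation over several
    # determinants and underestimate the 2-configuration mixing.
    from .engine.adapter import casci_wavefunction
    from .engine.casci import one_particle_rdm
    nmo = C.shape[1]
    C2 = C.copy()
    sig = sigma
    for _ in range(3):
        active = [sig] + list(range(nocc, nmo))
        wide = casci_wavefunction(geom, res.shells, C2, nocc, active,
                                  n_configs=nmo, basis_name=basis_name,
                                  scf_energy=res.energy)
        dets = [(d.alpha, d.beta) for d in wide.determinants]
        gamma = one_particle_rdm(dets, wide.ci_coefficients, nmo)
        sub = gamma[np.ix_(active, active)]
        w, U = np.linalg.eigh(sub)
        nat = C2[:, active] @ U
        C2[:, sig] = nat[:, -1]              # strongly occupied natural
        C2[:, nocc] = nat[:, -2]             # correlating natural
        # re-orthogonalise the remaining virtuals against the new pair
        rest = C2[:, nocc + 1:]
        from .engine.integrals import overlap as _overlap
        S = _overlap(res.shells, geom)
        for col in (sig, nocc):
            proj = (C2[:, col] @ S @ rest)
            rest = rest - np.outer(C2[:, col], proj)
        # Gram-Schmidt among themselves
        for j in range(rest.shape[1]):
            for k in range(j):
                rest[:, j] -= (rest[:, k] @ S @ rest[:, j]) * rest[:, k]
            rest[:, j] /= np.sqrt(rest[:, j] @ S @ rest[:, j])
        C2[:, nocc + 1:] = rest
    return casci_wavefunction(geom, res.shells, C2, nocc, (sig, nocc),
                              n_configs, basis_name=basis_name,
                              scf_energy=res.energy)


def bond_electron_feature(site, atom_position_bohr):
    """Indices of the alpha and beta electrons nearest a given nucleus.

    Identifies the bond pair of a converged site for feature-restricted
    bimodality detection (electron slots have no identity until a site
    assigns them one).
    """
    pos = site.positions
    d = np.linalg.norm(pos - np.asarray(atom_position_bohr), axis=1)
    ia = int(np.argmin(d[:site.n_alpha]))
    ib = site.n_alpha + int(np.argmin(d[site.n_alpha:]))
    return [ia, ib]


# --------------------------------------------------------------------------
# demonstration geometries (Angstrom)
# --------------------------------------------------------------------------

def demo_geometry(name: str, **kw) -> Geometry:
    """Geometries of the demonstration systems, by name.

    water and methyl use restricted-level 6-31G(d) optimised parameters;
    "hf" takes a bond length keyword r (Angstrom, default 0.911).
    """
    name = name.lower()
    if name == "water":
        # r(OH) = 0.947 A, HOH = 105.5 deg
        r, half = 0.9473, math.radians(105.5 / 2)
        return Geometry.from_angstrom(
            ["O", "H", "H"],
            [[0.0, 0.0, 0.0],
             [0.0, r * math.sin(half), r * math.cos(half)],
             [0.0, -r * math.sin(half), r * math.cos(half)]])
    if name == "hf":
        r = kw.get("r", 0.911)
        return Geometry.from_angstrom(["F", "H"],
                                      [[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    if name == "methyl":
        # planar D3h, r(CH) = 1.0736 A
        r = 1.0736
        pts = [[0.0, 0.0, 0.0]]
        for k in range(3):
            th = 2.0 * math.pi * k / 3.0
            pts.append([r * math.cos(th), r * math.sin(th), 0.0])
        return Geometry.from_angstrom(["C", "H", "H", "H"], pts,
                                      charge=0, multiplicity=2)
    if name == "n2":
        r = kw.get("r", 1.078)
        return Geometry.from_angstrom(["N", "N"],
                                      [[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    raise ValueError(f"unknown demo geometry {name!r}")
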