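"""The built-in electronic-structure engine.

Integrals are validated against grid quadrature and hydrogenic closed
forms; the SCF stack against frozen literature anchor energies; the small
CASCI against the exact Coulson-Fischer dissociation limit.
"""

import numpy as np
import pytest

from dvms.engine import (
    build_wavefunction, expectation_dipole, optimize_diatomic_bond_length,
    orbital_orthonormality_error, run_rhf, run_uhf,
)
from dvms.engine import integrals
from dvms.fixtures import demo_geometry, packaged_fixture
from dvms.wavefunction import BasisShell, Geometry, evaluate_basis

rng = np.random.default_rng(77)


@pytest.fixture(scope="module")
def gentle_shells():
    geom = Geometry(["O", "H"], np.array([[0.1, -0.2, 0.3],
                                          [1.2, 0.8, -0.5]]), 0, 2)
    shells = [
        BasisShell(0, 0, [0.5, 1.2], [0.7, 0.4]),
        BasisShell(0, 1, [0.8], [1.0]),
        BasisShell(0, 2, [0.9, 0.3], [0.6, 0.5]),
        BasisShell(1, 0, [0.35], [1.0]),
        BasisShell(1, 1, [0.5, 1.5], [0.5, 0.6]),
    ]
    return geom, shells


class TestIntegrals:
    def test_overlap_and_dipole_match_quadrature(self, gentle_shells):
        geom, shells = gentle_shells
        S = integrals.overlap(shells, geom)
        mu = integrals.dipole_matrices(shells, geom)
        x = np.linspace(-9, 9, 91)
        h = x[1] - x[0]
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        B = evaluate_basis(shells, geom, pts)
        assert np.abs(S - (B.T @ B) * h ** 3).max() < 1e-8
        for d in range(3):
            Dq = (B.T * pts[:, d]) @ B * h ** 3
            assert np.abs(mu[d] - Dq).max() < 1e-7

    def test_hydrogenic_eigenvalues(self):
        """T + V reproduces the exact 1s and 2p hydrogen energies in
        near-complete even-tempered bases."""
        for l, exact in [(0, -0.5), (1, -0.125)]:
            g = Geometry(["H"], np.zeros((1, 3)), 0, 2)
            sh = [BasisShell(0, l, [a], [1.0])
                  for a in np.geomspace(1e-3, 1e4, 26)]
            S = integrals.overlap(sh, g)
            H = integrals.kinetic(sh, g) + integrals.nuclear_attraction(sh, g)
            w, U = np.linalg.eigh(S)
            keep = w > 1e-10
            X = U[:, keep] / np.sqrt(w[keep])
            e0 = np.linalg.eigvalsh(X.T @ H @ X)[0]
            assert e0 == pytest.approx(exact, abs=2e-7)

    def test_eri_symmetry_and_positivity(self, gentle_shells):
        geom, shells = gentle_shells
        eri = integrals.electron_repulsion(shells, geom)
        assert np.allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-12)
        assert np.allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-12)
        n = eri.shape[0]
        # (ii|ii) Coulomb self-repulsions are positive
        assert all(eri[i, i, i, i] > 0 for i in range(n))


class TestSCF:
    def test_hydrogen_atom_energy(self):
        """Frozen split-valence literature value for the H atom."""
        g = Geometry(["H"], np.zeros((1, 3)), 0, 2)
        assert run_uhf(g, "6-31g").energy == pytest.approx(-0.4982329,
                                                           abs=1e-6)

    def test_water_energy_literature_anchor(self):
        geom = demo_geometry("water")
        res = run_rhf(geom)
        assert res.energy == pytest.approx(-76.0107, abs=5e-4)
        assert res.converged

    def test_virial_ratio(self):
        geom = demo_geometry("water")
        res = run_rhf(geom)
        T = integrals.kinetic(res.shells, geom)
        D = 2.0 * res.mo_coefficients[:, :res.n_alpha] \
            @ res.mo_coefficients[:, :res.n_alpha].T
        kin = np.sum(D * T)
        pot = res.energy - kin
        assert -pot / kin == pytest.approx(2.0, abs=5e-3)

    def test_occupied_orbitals_orthonormal(self):
        wf = packaged_fixture("water_rhf_631gd")
        assert orbital_orthonormality_error(wf) < 1e-6


class TestCASCI:
    def test_h2_dissociation_reaches_coulson_fischer_limit(self):
        """At 8 Angstrom the 2-configuration coefficients are exactly
        -/+ 1/sqrt(2)."""
        geom = Geometry.from_angstrom(["H", "H"], [[0, 0, 0], [0, 0, 8.0]])
        wf = build_wavefunction(geom, "6-31g", n_configs=2,
                                active_space=(2, 2))
        c = np.sort(np.abs(wf.ci_coefficients))
        assert np.allclose(c, [1 / np.sqrt(2)] * 2, atol=1e-4)

    def test_single_configuration_coefficient_is_one(self):
        geom = demo_geometry("hf", r=0.95)
        wf = build_wavefunction(geom, n_configs=1)
        assert np.allclose(wf.ci_coefficients, [1.0])

    def test_casci_lowers_energy_below_scf(self):
        geom = demo_geometry("hf", r=1.11)
        wf = build_wavefunction(geom, n_configs=2)
        assert wf.meta["casci_energy"] < wf.meta["scf_energy"]


class TestAdapter:
    def test_bond_length_optimisation_runs(self):
        r, e = optimize_diatomic_bond_length(["F", "H"],
                                             bounds_angstrom=(0.85, 1.0))
        assert 0.85 < r < 1.0

    def test_uhf_wavefunction_layout(self):
        wf = packaged_fixture("methyl_uhf_631gd")
        assert (wf.n_alpha, wf.n_beta) == (5, 4)
        # alpha and beta occupations address different orbital columns
        d = wf.determinants[0]
        assert set(d.alpha).isdisjoint(d.beta)

    def test_expectation_dipole_symmetric_molecule(self):
        """A homonuclear diatomic has zero dipole."""
        geom = Geometry.from_angstrom(["N", "N"], [[0, 0, 0], [0, 0, 1.1]])
        wf = build_wavefunction(geom)
        assert np.linalg.norm(expectation_dipole(wf)) < 1e-8
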