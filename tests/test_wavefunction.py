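"""Wavefunction evaluation: basis values, amplitudes, antisymmetry."""

import math

import numpy as np
import pytest

from dvms.fixtures import (
    h2_two_config_amplitude, make_h2_two_config, make_toy_determinant,
    packaged_fixture,
)
from dvms.wavefunction import (
    BasisShell, Geometry, cartesian_components, evaluate_basis,
    primitive_norm, shell_contraction_norm,
)

rng = np.random.default_rng(20260924)


class TestBasisEvaluation:
    def test_s_primitive_at_center_equals_normalisation(self):
        g = Geometry(["H"], np.zeros((1, 3)), 0, 2)
        sh = BasisShell(0, 0, [1.0], [1.0])
        v = evaluate_basis([sh], g, np.zeros((1, 3)))[0, 0]
        expect = primitive_norm(1.0, 0) * shell_contraction_norm(sh)
        assert v == pytest.approx(expect, rel=1e-14)

    def test_gaussian_decay_far_from_center(self):
        g = Geometry(["O"], np.zeros((1, 3)), 0, 3)
        for l in (0, 1, 2):
            sh = BasisShell(0, l, [0.3, 2.0], [0.7, 0.5])
            v = evaluate_basis([sh], g, np.array([[50.0, 0.0, 0.0]]))
            assert np.all(np.abs(v) < 1e-30)

    def test_contracted_shell_matches_primitive_summation(self):
        """Term-by-term primitive summation oracle for a 6-31G(d) oxygen
        s shell at a probe point."""
        from dvms.engine.basis_data import shells_for_element
        g = Geometry(["O"], np.zeros((1, 3)), 0, 3)
        l, prims = shells_for_element("O")[0]
        sh = BasisShell(0, l, [p[0] for p in prims], [p[1] for p in prims])
        pt = np.array([[0.4, -0.3, 0.7]])
        r2 = float((pt ** 2).sum())
        total = sum(c * primitive_norm(a, 0) * math.exp(-a * r2)
                    for a, c in prims)
        total *= shell_contraction_norm(sh)
        assert evaluate_basis([sh], g, pt)[0, 0] == pytest.approx(
            total, rel=1e-13)

    def test_unsupported_angular_momentum_raises(self):
        with pytest.raises(NotImplementedError):
            BasisShell(0, 4, [1.0], [1.0])

    def test_normalisation_by_quadrature(self):
        """Each contracted Cartesian component integrates to unit norm."""
        g = Geometry(["C"], np.zeros((1, 3)), 0, 3)
        shells = [BasisShell(0, 0, [0.5, 1.5], [0.6, 0.5]),
                  BasisShell(0, 1, [0.8], [1.0]),
                  BasisShell(0, 2, [0.7, 0.25], [0.4, 0.7])]
        x = np.linspace(-8, 8, 81)
        h = x[1] - x[0]
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        B = evaluate_basis(shells, g, pts)
        norms = (B ** 2).sum(axis=0) * h ** 3
        assert np.allclose(norms, 1.0, atol=2e-6)


class TestAmplitude:
    @pytest.fixture(scope="class")
    def water(self):
        return packaged_fixture("water_rhf_631gd")

    def test_antisymmetry_under_like_spin_transposition(self, water):
        n, na = water.n_electrons, water.n_alpha
        for _ in range(200):
            x = rng.normal(scale=1.5, size=(n, 3))
            a0 = water.amplitude(x)
            spin = rng.integers(2)
            lo, hi = (0, na) if spin == 0 else (na, n)
            i, j = rng.choice(np.arange(lo, hi), 2, replace=False)
            y = x.copy()
            y[[i, j]] = y[[j, i]]
            assert water.amplitude(y) == pytest.approx(-a0, rel=1e-10)

    def test_like_spin_coincidence_gives_zero(self, water):
        x = rng.normal(scale=1.5, size=(water.n_electrons, 3))
        x[1] = x[0]          # two alpha electrons at the identical point
        assert abs(water.amplitude(x)) < 1e-12

    def test_density_is_square_and_permutation_invariant(self, water):
        n, na = water.n_electrons, water.n_alpha
        x = rng.normal(scale=1.5, size=(100, n, 3))
        amps = water.amplitude_many(x)
        assert np.allclose(water.density_many(x), amps ** 2, rtol=1e-12)
        perm_a = rng.permutation(na)
        perm_b = na + rng.permutation(n - na)
        xp = x[:, np.concatenate([perm_a, perm_b]), :]
        assert np.allclose(water.density_many(xp), amps ** 2, rtol=1e-9)

    def test_single_electron_amplitude_is_orbital_value(self):
        wf = make_toy_determinant([[0.5, -0.3, 0.2]], width=1.3)
        pts = rng.normal(size=(20, 3))
        bas = wf.basis_values(pts)
        orb = bas @ wf.mo_coefficients[:, 0]
        amps = wf.amplitude_many(pts[:, None, :])
        assert np.allclose(amps, orb, rtol=1e-12)

    def test_cofactor_expansion_oracle(self, water):
        """Production LU-based determinants vs a textbook cofactor
        expansion, for Slater matrices up to 5x5."""

        def cofactor_det(M):
            n = len(M)
            if n == 1:
                return M[0, 0]
            return sum((-1) ** j * M[0, j]
                       * cofactor_det(np.delete(M[1:], j, axis=1))
                       for j in range(n))

        n, na = water.n_electrons, water.n_alpha
        for _ in range(5):
            x = rng.normal(scale=1.5, size=(n, 3))
            bas = water.basis_values(x)
            total = 0.0
            for det, c in zip(water.determinants, water.ci_coefficients):
                A = bas[:na] @ water.mo_coefficients[:, list(det.alpha)]
                B = bas[na:] @ water.mo_coefficients[:, list(det.beta)]
                total += c * cofactor_det(A) * cofactor_det(B)
            assert water.amplitude(x) == pytest.approx(total, rel=1e-10)

    def test_dimension_mismatch_raises(self, water):
        with pytest.raises(ValueError):
            water.amplitude(np.zeros((3, 3)))


class TestTwoConfigH2:
    def test_single_configuration_limit(self):
        wf1 = make_h2_two_config(1.0, 1.0, 0.0)
        assert len(wf1.determinants) == 1
        x = rng.normal(size=(2, 3))
        assert wf1.amplitude(x) == pytest.approx(
            h2_two_config_amplitude(wf1, x[0], x[1]), rel=1e-12)

    def test_covalent_mix_cancels_ionic_terms(self):
        """Expanding c_g sg sg + c_u su su over atomic orbitals, the ionic
        products (both electrons on one nucleus) cancel exactly when
        c_g n_g^2 = -c_u n_u^2 (n_g, n_u the overlap-dependent molecular
        orbital normalisations); equal weights do the same in the
        zero-overlap limit."""
        from dvms.engine.integrals import overlap as _ov
        R = 3.0                       # weak overlap: AO tails negligible
        probe = make_h2_two_config(R, 1.0, 0.0)
        s01 = _ov(probe.shells, probe.geometry)[0, 1]
        ng2 = 1.0 / (2.0 * (1.0 + s01))
        nu2 = 1.0 / (2.0 * (1.0 - s01))
        norm = math.hypot(nu2, ng2)
        nuc = probe.geometry.coords[0]
        ion_point = np.stack([nuc, nuc])
        cov_point = np.stack(list(probe.geometry.coords))
        # single determinant: large ionic amplitude
        assert abs(probe.amplitude(ion_point)) > 1e-3
        # exact mix: ionic coefficient vanishes identically, only the
        # exponentially small AO tail remains; equal weights leave an O(S)
        # ionic residue -- both orders of magnitude below the reference
        for cg, cu, tol in [(nu2 / norm, -ng2 / norm, 1e-6),
                            (1 / math.sqrt(2), -1 / math.sqrt(2), 1e-4)]:
            wf = make_h2_two_config(R, cg, cu)
            assert abs(wf.amplitude(ion_point)) < tol
            assert abs(wf.amplitude(cov_point)) > 1e-4

    def test_amplitude_matches_closed_form(self):
        wf = make_h2_two_config(1.4, math.sqrt(0.8), -math.sqrt(0.2))
        for _ in range(25):
            r1, r2 = rng.normal(scale=2.0, size=(2, 3))
            assert wf.amplitude(np.stack([r1, r2])) == pytest.approx(
                h2_two_config_amplitude(wf, r1, r2), rel=1e-11, abs=1e-15)

    def test_unnormalised_coefficients_rejected(self):
        with pytest.raises(ValueError):
            make_h2_two_config(1.0, 0.9, 0.5)


class TestToyDeterminant:
    def test_duplicate_same_spin_center_rejected(self):
        with pytest.raises(ValueError):
            make_toy_determinant([[0, 0, 0], [0, 0, 0]], spins="aa")

    def test_opposite_spin_coincident_centers_allowed(self):
        wf = make_toy_determinant([[0, 0, 0], [0, 0, 0]], spins="ab")
        assert wf.n_alpha == wf.n_beta == 1
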