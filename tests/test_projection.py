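"""Tile projections: electron sites, cross-sections, marginals, dipole."""

import math

import numpy as np
import pytest

from dvms.fixtures import make_toy_determinant
from dvms.projection import (
    ScalarField, cross_section_field, dipole_check, electron_sites,
    extract_isosurface, marginal_density, write_cube, write_obj,
)
from dvms.sampler import SamplerConfig, VoronoiSite, run_dvms, sample_tile
from dvms.units import ANGSTROM_PER_BOHR

rng = np.random.default_rng(31415)


class TestElectronSites:
    def test_single_electron_site_units_and_order(self):
        pos = np.array([[1.0, -2.0, 0.5]])
        site = VoronoiSite(pos, 1, 0)
        es = electron_sites(site)
        assert len(es) == 1 and es[0].spin == "alpha"
        assert np.allclose(es[0].position, pos[0] * ANGSTROM_PER_BOHR)

    def test_centroid_identity(self):
        pos = rng.normal(size=(6, 3))
        site = VoronoiSite(pos, 3, 3)
        es = electron_sites(site)
        centroid = np.mean([e.position for e in es], axis=0)
        assert np.allclose(centroid, pos.mean(axis=0) * ANGSTROM_PER_BOHR)
        assert [e.spin for e in es] == ["alpha"] * 3 + ["beta"] * 3


class TestCrossSection:
    @pytest.fixture(scope="class")
    def one_electron(self):
        wf = make_toy_determinant([[0.0, 0.0, 0.0]], width=1.0)
        site = VoronoiSite(np.zeros((1, 3)), 1, 0)
        return wf, site

    def test_one_electron_field_equals_orbital(self, one_electron):
        wf, site = one_electron
        field = cross_section_field(wf, site, 0, spacing=0.4, margin=2.5)
        pts = np.stack(np.meshgrid(*[field.axis_points(d) for d in range(3)],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        orb = wf.amplitude_many(
            (pts / ANGSTROM_PER_BOHR)[:, None, :])
        assert np.allclose(field.values.ravel(), orb, atol=1e-12)

    def test_field_at_site_equals_amplitude(self):
        wf = make_toy_determinant([[-4, 0, 0], [4, 0, 0]], width=1.0)
        site = VoronoiSite(np.array([[-4.0, 0, 0], [4.0, 0, 0]]), 2, 0)
        field = cross_section_field(wf, site, 0, spacing=0.35, margin=2.0)
        # nearest grid point to the site's electron-0 position
        target = site.positions[0] * ANGSTROM_PER_BOHR
        idx = tuple(int(round((target[d] - field.origin[d]) / field.spacing))
                    for d in range(3))
        x = site.positions.copy()
        x[0] = (field.origin + np.array(idx) * field.spacing) \
            / ANGSTROM_PER_BOHR
        assert field.values[idx] == pytest.approx(wf.amplitude(x), rel=1e-9)

    def test_clamped_field_is_sign_uniform_inside(self):
        wf = make_toy_determinant([[-4, 0, 0], [4, 0, 0]], width=1.0)
        site_pos = np.array([[-4.0, 0, 0], [4.0, 0, 0]])
        sign = int(np.sign(wf.amplitude(site_pos)))
        site = VoronoiSite(site_pos, 2, 0, sign)
        field = cross_section_field(wf, site, 0, spacing=0.4, margin=3.0)
        v = field.values.ravel() * sign
        assert v.min() >= -1e-12


class TestIsosurface:
    def test_spherical_gaussian_radius_closed_form(self):
        """Marching-cubes vertices of exp(-r^2/2w^2) at level zeta sit at
        r = w sqrt(2 ln(max/zeta)) within a grid spacing."""
        w = 0.8
        x = np.linspace(-3, 3, 41)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        vals = np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * w ** 2))
        field = ScalarField(np.array([-3.0, -3, -3]), x[1] - x[0], vals)
        zeta = 0.1
        surf = extract_isosurface(field, zeta)
        r = np.linalg.norm(surf.vertices, axis=1)
        expect = w * math.sqrt(2 * math.log(1.0 / zeta))
        assert np.all(np.abs(r - expect) < field.spacing)

    def test_isovalue_outside_range_raises(self):
        field = ScalarField(np.zeros(3), 0.1, np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            extract_isosurface(field, 2.0)

    def test_default_isovalue_is_tenth_of_maximum(self):
        x = np.linspace(-3, 3, 31)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        vals = 5.0 * np.exp(-(X ** 2 + Y ** 2 + Z ** 2))
        field = ScalarField(np.array([-3.0, -3, -3]), x[1] - x[0], vals)
        surf = extract_isosurface(field)
        assert surf.isovalue == pytest.approx(0.5)


class TestMarginalDensity:
    @pytest.fixture(scope="class")
    def sampled_toy(self):
        wf = make_toy_determinant([[0.3, 0, 0]], width=1.0)
        cfg = SamplerConfig(n_walkers=500, max_sweeps=500, seed=12)
        sites, cloud, _ = run_dvms(wf, cfg)
        samples, _ = sample_tile(wf, sites, cloud, cfg, 40,
                                 np.random.default_rng(3))
        return wf, samples

    def test_unit_integral(self, sampled_toy):
        wf, samples = sampled_toy
        field = marginal_density(samples, 0, geometry=wf.geometry,
                                 spacing=0.25, margin=3.0)
        total = field.values.sum() * field.spacing ** 3
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_orbital_density(self, sampled_toy):
        """The histogram estimates |phi|^2 (quadrature oracle) within
        sampling error."""
        wf, samples = sampled_toy
        field = marginal_density(samples, 0, geometry=wf.geometry,
                                 spacing=0.35, margin=2.5)
        pts = np.stack(np.meshgrid(*[field.axis_points(d) for d in range(3)],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        dens = wf.density_many((pts / ANGSTROM_PER_BOHR)[:, None, :])
        dens = dens.reshape(field.values.shape)
        dens /= dens.sum() * field.spacing ** 3
        big = dens > 0.02 * dens.max()
        rel = np.abs(field.values[big] - dens[big]) / dens.max()
        assert np.quantile(rel, 0.95) < 0.1


class TestDipole:
    def test_toy_displaced_gaussians_closed_form(self):
        """Site dipole and expectation dipole both equal the analytic
        centroid sum for well-separated displaced Gaussians."""
        centers = np.array([[-5.0, 0, 0], [5.0, 1.0, 0]])
        wf = make_toy_determinant(centers, width=0.9, spins="ab")
        site = VoronoiSite(centers, 1, 1)
        mu_s, mu_e, diff = dipole_check(site, wf)
        nuc = wf.geometry.coords.sum(axis=0)     # Z=1 pseudo-nuclei
        expect = nuc - centers.sum(axis=0)
        assert np.allclose(mu_s, expect, atol=1e-12)
        assert np.allclose(mu_e, expect, atol=1e-6)

    def test_water_dipole_site_vs_expectation(self, water_runs, water_wf):
        """Charge-weighted nuclei minus summed electron sites reproduces
        <Psi|mu|Psi> within three standard errors across runs."""
        dips = []
        for run in water_runs:
            mu_s, mu_e, _ = dipole_check(run["sites"][0], water_wf)
            dips.append(mu_s)
        dips = np.stack(dips)
        sem = dips.std(axis=0, ddof=1) / math.sqrt(len(dips))
        from dvms.engine import expectation_dipole
        mu_e = expectation_dipole(water_wf)
        resid = np.abs(dips.mean(axis=0) - mu_e)
        assert np.all(resid < 3 * sem + 1e-3)


class TestExports:
    def test_cube_and_obj_roundtrip_files(self, tmp_path):
        wf = make_toy_determinant([[0, 0, 0]], width=1.0)
        site = VoronoiSite(np.zeros((1, 3)), 1, 0)
        field = cross_section_field(wf, site, 0, spacing=0.5, margin=2.0)
        cube = tmp_path / "f.cube"
        write_cube(cube, field, wf.geometry)
        lines = cube.read_text().splitlines()
        assert int(lines[2].split()[0]) == 1          # one pseudo-atom
        surf = extract_isosurface(field)
        obj = tmp_path / "f.obj"
        write_obj(obj, surf)
        text = obj.read_text()
        assert text.count("\nv ") + text.startswith("v ") \
            == len(surf.vertices)
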