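"""DVMS sampling: centroid recovery, detailed balance, tile containment."""

import math

import numpy as np
import pytest
from scipy import stats

from dvms.fixtures import make_toy_determinant
from dvms.permutations import in_tile
from dvms.sampler import (
    SamplerConfig, SiteStarvationError, VoronoiSite, WalkerCloud,
    initialize_walkers, run_dvms, sample_tile, site_uncertainty,
    update_sites, match_site_labels,
)

rng = np.random.default_rng(5150)


def _repeat_runs(wf, n_runs, base_seed, **cfg_kw):
    sites_list = []
    for k in range(n_runs):
        cfg = SamplerConfig(seed=base_seed + 31 * k, **cfg_kw)
        sites, cloud, diag = run_dvms(wf, cfg)
        sites_list.append(sites[0].positions)
    return sites_list


class TestOneElectron:
    @pytest.fixture(scope="class")
    def toy(self):
        return make_toy_determinant([[0.4, -0.2, 0.3]], width=1.1)

    def test_site_matches_quadrature_centroid(self, toy):
        """DVMS site vs the grid-quadrature centroid of |phi|^2, within
        three standard errors over independent runs."""
        runs = _repeat_runs(toy, 5, 100, n_walkers=300, max_sweeps=900)
        stack = np.stack(runs)
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / math.sqrt(len(runs))
        x = np.linspace(-7, 7.8, 75)
        h = x[1] - x[0]
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        dens = toy.density_many(pts[:, None, :])
        centroid = (pts * dens[:, None]).sum(axis=0) / dens.sum()
        assert np.all(np.abs(mean[0] - centroid) < 3 * sem[0] + 1e-6)

    def test_sampled_marginal_matches_orbital_density(self, toy):
        """Chi-square goodness of fit of the sampled x-marginal against
        |phi|^2 at 1e5 thinned samples (p > 0.01, fixed seed)."""
        cfg = SamplerConfig(n_walkers=1000, max_sweeps=700, seed=42)
        sites, cloud, diag = run_dvms(toy, cfg)
        chunks = []
        g = np.random.default_rng(7)
        while sum(len(c) for c in chunks) < 100000:
            s, _ = sample_tile(toy, sites, cloud, cfg, 1, g)
            chunks.append(s[:, 0, 0])      # x coordinate
            for _ in range(9):             # thin: decorrelate between grabs
                sample_tile(toy, sites, cloud, cfg, 1, g)
        xs = np.concatenate(chunks)[:100000]
        center, width = 0.4, 1.1
        edges = center + width * np.linspace(-3.2, 3.2, 17)
        obs, _ = np.histogram(xs, bins=edges)
        cdf = stats.norm(center, width / math.sqrt(2)).cdf  # |phi|^2 width
        probs = np.diff(cdf(edges))
        mask = np.ones(len(obs), bool)
        expected = probs / probs.sum() * obs.sum()
        chi2, p = stats.chisquare(obs[mask], expected[mask])
        assert p > 0.01

    def test_no_permutation_images_for_single_electron(self, toy):
        cfg = SamplerConfig(n_walkers=50, max_sweeps=120, seed=0)
        sites, cloud, _ = run_dvms(toy, cfg)
        inside, _ = in_tile(cloud.positions[0], [sites[0].positions], 1, 0)
        assert inside


class TestToyRecovery:
    def test_two_separated_alpha_electrons(self):
        """Sites recover the generating centers (+-5, 0, 0) within three
        standard errors; oracle: restricted 6D quadrature of the explicit
        two-electron tile centroid."""
        centers = np.array([[-5.0, 0, 0], [5.0, 0, 0]])
        wf = make_toy_determinant(centers, width=1.0)
        runs = _repeat_runs(wf, 5, 300, n_walkers=400, max_sweeps=1200)
        ref = runs[0]
        aligned = [ref] + [match_site_labels(ref, r, 2, 0)[0]
                           for r in runs[1:]]
        stack = np.stack(aligned)
        mean, sem = stack.mean(axis=0), \
            stack.std(axis=0, ddof=1) / math.sqrt(5)
        # quadrature oracle on box_A x box_B (the tile of the unswapped
        # assignment; well-separated centers make it exact)
        x = np.linspace(-4.0, 4.0, 17)
        h = x[1] - x[0]
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        gA = np.stack([X.ravel() - 5.0, Y.ravel(), Z.ravel()], axis=-1)
        gB = gA + [10.0, 0.0, 0.0]
        basA = wf.basis_values(gA) @ wf.mo_coefficients
        basB = wf.basis_values(gB) @ wf.mo_coefficients
        psi = np.outer(basA[:, 0], basB[:, 1]) \
            - np.outer(basA[:, 1], basB[:, 0])
        w = np.where(psi > 0, psi ** 2, 0.0)
        tot = w.sum()
        cA = (w.sum(axis=1)[:, None] * gA).sum(axis=0) / tot
        cB = (w.sum(axis=0)[:, None] * gB).sum(axis=0) / tot
        order = np.argsort(mean[:, 0])
        expect = np.stack([cA, cB])[np.argsort([cA[0], cB[0]])]
        assert np.all(np.abs(mean[order] - expect) < 3 * sem[order] + 0.02)

    def test_equilateral_triangle_c3_symmetry(self):
        """Three alpha electrons at triangle vertices: the converged site
        reproduces the triangle up to relabelling, C3-symmetric within
        error of the mean."""
        r = 5.0
        verts = np.array([[r * math.cos(2 * math.pi * k / 3),
                           r * math.sin(2 * math.pi * k / 3), 0.0]
                          for k in range(3)])
        wf = make_toy_determinant(verts, width=1.0)
        runs = _repeat_runs(wf, 3, 900, n_walkers=400, max_sweeps=1200)

        def align_any_parity(ref, other):
            # independent runs may converge in either mirror tile; for the
            # structural comparison any relabelling is legitimate
            from scipy.optimize import linear_sum_assignment
            C = ((ref[:, None, :] - other[None, :, :]) ** 2).sum(-1)
            _, cols = linear_sum_assignment(C)
            return other[cols]

        ref = runs[0]
        aligned = [ref] + [align_any_parity(ref, x) for x in runs[1:]]
        stack = np.stack(aligned)
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / math.sqrt(3)
        verts_matched = align_any_parity(mean, verts)
        assert np.all(np.abs(mean - verts_matched) < 3 * sem + 0.03)


class TestTileContainment:
    def test_all_walkers_inside_after_sweeps(self):
        wf = make_toy_determinant([[-3, 0, 0], [3, 0, 0], [0, 3, 0]],
                                  width=1.0, spins="aab")
        cfg = SamplerConfig(n_walkers=200, max_sweeps=400, seed=8)
        sites, cloud, _ = run_dvms(wf, cfg)
        site_pos = [s.positions for s in sites]
        for k in range(cloud.size):
            inside, _ = in_tile(cloud.positions[k], site_pos, 2, 1)
            assert inside

    def test_reject_policy_also_contains(self):
        wf = make_toy_determinant([[-3, 0, 0], [3, 0, 0]], width=1.0)
        cfg = SamplerConfig(n_walkers=150, max_sweeps=300, seed=8,
                            fold_policy="reject")
        sites, cloud, _ = run_dvms(wf, cfg)
        for k in range(0, cloud.size, 5):
            inside, _ = in_tile(cloud.positions[k], [sites[0].positions],
                                2, 0)
            assert inside


class TestReproducibility:
    def test_same_seed_identical_sites(self):
        wf = make_toy_determinant([[-4, 0, 0], [4, 0, 0]], width=1.0)
        cfg = SamplerConfig(n_walkers=100, max_sweeps=250, seed=21)
        s1, _, _ = run_dvms(wf, cfg)
        s2, _, _ = run_dvms(wf, cfg)
        assert np.array_equal(s1[0].positions, s2[0].positions)

    def test_permuted_initial_site_gives_permuted_final_site(self):
        """Relabelling the initial site by a same-sign permutation yields
        the relabelled result: the physics is permutation-covariant, so
        the two runs agree after alignment within Monte-Carlo error (the
        noise stream itself is not permutation-covariant, so agreement is
        statistical, not bitwise)."""
        wf = make_toy_determinant([[-4, 0, 0], [4, 0, 0], [0, 4, 0]],
                                  width=1.0)
        site0 = np.array([[-4.1, 0, 0], [4.1, 0, 0], [0, 4.1, 0]])
        perm = [1, 2, 0]                      # even 3-cycle
        cfg = SamplerConfig(n_walkers=300, max_sweeps=800, seed=4)
        a, _, _ = run_dvms(wf, cfg, [VoronoiSite(site0, 3, 0)])
        b, _, _ = run_dvms(wf, cfg, [VoronoiSite(site0[perm], 3, 0)])
        aligned, sp = match_site_labels(a[0].positions, b[0].positions,
                                        3, 0)
        assert sp.sign == 1
        assert np.allclose(aligned, a[0].positions, atol=0.15)


class TestSiteBookkeeping:
    def test_update_sites_identical_walkers(self):
        x = rng.normal(size=(1, 4, 3))
        pos = np.repeat(x, 50, axis=0)
        cloud = WalkerCloud(pos, np.zeros(50), np.ones(50),
                            np.zeros(50, int), 2, 2)
        sites = [VoronoiSite(x[0], 2, 2)]
        new = update_sites(cloud, sites)
        assert np.allclose(new[0].positions, x[0])

    def test_starvation_raises(self):
        pos = rng.normal(size=(10, 2, 3))
        cloud = WalkerCloud(pos, np.zeros(10), np.ones(10),
                            np.zeros(10, int), 1, 1)
        sites = [VoronoiSite(pos[0], 1, 1), VoronoiSite(pos[1] + 9, 1, 1)]
        with pytest.raises(SiteStarvationError):
            update_sites(cloud, sites)

    def test_initialized_walkers_start_inside_with_tile_sign(self):
        wf = make_toy_determinant([[-3, 0, 0], [3, 0, 0]], width=1.0)
        site = VoronoiSite(np.array([[-3.0, 0, 0], [3.0, 0, 0]]), 2, 0,
                           sign=int(np.sign(wf.amplitude(
                               np.array([[-3.0, 0, 0], [3.0, 0, 0]])))))
        cfg = SamplerConfig(n_walkers=80, max_sweeps=10, seed=1)
        cloud = initialize_walkers(wf, [site], cfg,
                                   np.random.default_rng(1))
        assert np.all(cloud.sign == site.sign)
        for k in range(cloud.size):
            inside, _ = in_tile(cloud.positions[k], [site.positions], 2, 0)
            assert inside


class TestSiteUncertainty:
    def test_identical_runs_zero_sem(self):
        s = rng.normal(size=(4, 3))
        sem, mean = site_uncertainty([s, s.copy(), s.copy()], 2, 2)
        assert np.allclose(sem, 0.0)

    def test_even_relabelling_gives_zero_sem(self):
        s = rng.normal(size=(4, 3))
        relabelled = s[[1, 0, 3, 2]]          # even: one swap per spin
        sem, mean = site_uncertainty([s, relabelled], 2, 2)
        assert np.allclose(sem, 0.0, atol=1e-12)

    def test_sem_consistent_with_within_run_variance(self):
        """SEM across 5 independent toy runs agrees with the within-run
        variance / effective-sample-size estimate within a factor of 3."""
        wf = make_toy_determinant([[0.0, 0, 0]], width=1.0)
        runs = []
        spreads = []
        sweeps_used = []
        for k in range(5):
            cfg = SamplerConfig(n_walkers=200, max_sweeps=600,
                                seed=700 + k)
            sites, cloud, diag = run_dvms(wf, cfg)
            runs.append(sites[0].positions)
            spreads.append(cloud.positions[:, 0, :].std())
            sweeps_used.append(diag.outer_iterations
                               * cfg.sweeps_per_iteration)
        sem, _ = site_uncertainty(runs, 1, 0)
        # the site accumulates ~n_walkers x post-burn-in sweeps correlated
        # samples; tau ~ 5 sweeps gives the effective count
        n_eff = 200 * np.mean(sweeps_used) / 5.0
        predicted = np.mean(spreads) / math.sqrt(n_eff)
        ratio = sem.mean() / predicted
        assert 1 / 3 < ratio < 3
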