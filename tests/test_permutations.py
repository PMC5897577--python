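"""Same-sign permutations and the Voronoi membership predicate."""

import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from dvms._lap import _lap
from dvms.permutations import (
    SpinPermutation, apply_permutation, enumerate_same_sign_permutations,
    in_tile, nearest_same_sign_image, permutation_sign,
)

rng = np.random.default_rng(1234)


def inversion_count_sign(p):
    inv = sum(1 for i in range(len(p)) for j in range(i + 1, len(p))
              if p[i] > p[j])
    return -1 if inv % 2 else 1


class TestSign:
    def test_identity_and_transposition(self):
        assert SpinPermutation((0, 1, 2), (0, 1)).sign == 1
        assert SpinPermutation((1, 0, 2), (0, 1)).sign == -1

    def test_cycle_sign_matches_inversion_counting(self):
        for _ in range(300):
            n = rng.integers(1, 9)
            p = rng.permutation(n)
            assert permutation_sign(p) == inversion_count_sign(p)

    def test_malformed_permutation_rejected(self):
        with pytest.raises(ValueError):
            permutation_sign([0, 0, 1])


class TestEnumeration:
    @pytest.mark.parametrize("na,nb,count", [
        (2, 0, 1), (3, 0, 3), (2, 2, 2), (1, 1, 1), (4, 0, 12),
    ])
    def test_same_sign_counts(self, na, nb, count):
        perms = enumerate_same_sign_permutations(na, nb)
        assert len(perms) == count
        assert all(p.sign == 1 for p in perms)

    def test_count_formula_when_odd_permutations_exist(self):
        for na, nb in [(2, 1), (3, 2), (2, 3), (4, 2)]:
            expect = math.factorial(na) * math.factorial(nb) // 2
            assert len(enumerate_same_sign_permutations(na, nb)) == expect

    def test_size_guard(self):
        with pytest.raises(ValueError):
            enumerate_same_sign_permutations(10, 10)


class TestNearestImage:
    def test_exact_site_position_is_identity_with_zero_distance(self):
        x = rng.normal(size=(5, 3))
        r = nearest_same_sign_image(x, x, 3, 2)
        assert r.is_identity and r.squared_distance == 0.0

    def test_two_alpha_electrons_always_identity(self):
        """With N_alpha = 2 and no beta, the only even permutation is the
        identity (the 2-element swap is odd)."""
        for _ in range(50):
            x, s = rng.normal(size=(2, 2, 3))
            r = nearest_same_sign_image(x, s, 2, 0)
            assert r.is_identity

    def test_three_cycle_recovered_on_rotated_triangle(self):
        site = np.array([[1.0, 0, 0], [-0.5, math.sqrt(3) / 2, 0],
                         [-0.5, -math.sqrt(3) / 2, 0]])
        x = site[[1, 2, 0]]          # rotate by one vertex: an even 3-cycle
        r = nearest_same_sign_image(x, site, 3, 0)
        assert r.squared_distance == pytest.approx(0.0, abs=1e-12)
        oracle = nearest_same_sign_image(x, site, 3, 0, method="enumerate")
        assert r.squared_distance == pytest.approx(oracle.squared_distance)

    def test_assignment_matches_exhaustive_oracle(self):
        """1000 random (configuration, site) pairs, N_sigma <= 4: the
        assignment + parity search equals brute-force enumeration."""
        for _ in range(1000):
            na = int(rng.integers(1, 5))
            nb = int(rng.integers(0, 5))
            x = rng.normal(size=(na + nb, 3))
            s = rng.normal(size=(na + nb, 3))
            fast = nearest_same_sign_image(x, s, na, nb)
            slow = nearest_same_sign_image(x, s, na, nb, method="enumerate")
            assert fast.squared_distance == pytest.approx(
                slow.squared_distance, rel=1e-12, abs=1e-12)
            assert fast.is_identity == slow.is_identity

    def test_metric_symmetry(self):
        """Distance to image P o site equals distance from P^-1 o x to the
        site."""
        for _ in range(100):
            na, nb = 3, 2
            x = rng.normal(size=(5, 3))
            s = rng.normal(size=(5, 3))
            r = nearest_same_sign_image(x, s, na, nb)
            perm = r.permutation
            y = apply_permutation(x, perm)      # P^-1-relabelled x
            d = float(((y - s) ** 2).sum())
            assert d == pytest.approx(r.squared_distance, rel=1e-12,
                                      abs=1e-12)


class TestInTile:
    def test_at_site_position(self):
        sites = [rng.normal(size=(4, 3)) for _ in range(3)]
        inside, idx = in_tile(sites[1], sites, 2, 2)
        assert inside and idx == 1

    def test_boundary_tie_counts_as_inside(self):
        site = rng.normal(size=(3, 3))
        images = enumerate_same_sign_permutations(3, 0)
        nonid = [p for p in images if not p.is_identity][0]
        image = site[list(nonid.alpha)]
        midpoint = 0.5 * (site + image)
        inside, _ = in_tile(midpoint, [site], 3, 0)
        assert inside

    def test_matches_exhaustive_oracle_two_sites(self):
        for _ in range(300):
            na = int(rng.integers(1, 4))
            nb = int(rng.integers(0, 4))
            x = rng.normal(size=(na + nb, 3))
            sites = [rng.normal(size=(na + nb, 3)) for _ in range(2)]
            assert in_tile(x, sites, na, nb) == \
                in_tile(x, sites, na, nb, method="enumerate")


class TestCompiledAssignment:
    def test_lap_matches_scipy(self):
        for _ in range(300):
            n = int(rng.integers(1, 13))
            C = rng.normal(size=(n, n)) ** 2
            p, c = _lap(C)
            r, cols = linear_sum_assignment(C)
            assert c == pytest.approx(C[r, cols].sum(), rel=1e-12)
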