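"""Observable correctness against brute-force and constructed-geometry oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pchsim as ps
from pchsim.model import SPECIES_INDEX
from pchsim.observables import CLUSTER_CUTOFF

from conftest import dense_ball, dense_shell, packed_ball, packed_shell


def union_find_clusters(positions, cutoff):
    """Independent O(n^2) union-find connectivity oracle."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n - 1):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            if d @ d <= cutoff * cutoff:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    groups = {}
    for i, r in enumerate(roots):
        groups.setdefault(r, []).append(i)
    return sorted(map(sorted, groups.values()))


class TestFindClusters:
    def test_far_beads_are_singletons(self):
        pos = np.diag([10.0, 20.0, 30.0])
        cs = ps.find_clusters(pos, cutoff=1.5)
        assert cs.n_clusters == 3 and cs.largest_fraction() == pytest.approx(1 / 3)

    def test_chain_within_cutoff_is_one_cluster(self):
        pos = np.array([[1.2 * i, 0, 0] for i in range(10)])
        cs = ps.find_clusters(pos, cutoff=1.5)
        assert cs.n_clusters == 1

    def test_matches_union_find_oracle(self, rng):
        pos = rng.uniform(-5, 5, size=(300, 3))
        cs = ps.find_clusters(pos, cutoff=1.5)
        ours = sorted(sorted(map(int, cs.indices[cs.labels == k]))
                      for k in range(cs.n_clusters))
        assert ours == union_find_clusters(pos, 1.5)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=2, max_value=120))
    def test_union_find_property(self, seed, n):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-4, 4, size=(n, 3))
        cs = ps.find_clusters(pos, cutoff=1.2)
        ours = sorted(sorted(map(int, cs.indices[cs.labels == k]))
                      for k in range(cs.n_clusters))
        assert ours == union_find_clusters(pos, 1.2)

    def test_empty_subset(self):
        cs = ps.find_clusters(np.zeros((0, 3)))
        assert cs.n_clusters == 0

    def test_deterministic_label_order(self):
        pos = np.array([[0, 0, 0], [10, 0, 0], [10.5, 0, 0], [0.5, 0, 0.0]])
        cs = ps.find_clusters(pos, cutoff=1.0)
        # cluster 0 must contain the lowest bead index
        assert 0 in cs.indices[cs.labels == 0]


class TestIsCondensed:
    def test_single_cluster(self):
        cs = ps.find_clusters(np.array([[0, 0, 0], [1, 0, 0.0]]), 1.5)
        cond, frac, _ = ps.is_condensed(cs, 2)
        assert cond and frac == 1.0

    def test_all_singletons(self):
        cs = ps.find_clusters(np.diag([5.0, 10.0, 15.0]), 1.5)
        cond, frac, _ = ps.is_condensed(cs, 3)
        assert not cond and frac == pytest.approx(1 / 3)

    def test_boundary_half_is_condensed(self):
        # 2 of 4 beads clustered: fraction exactly 0.5, inclusive rule
        pos = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0], [20, 0, 0.0]])
        cs = ps.find_clusters(pos, 1.5)
        cond, frac, _ = ps.is_condensed([cs, cs, cs], 4)
        assert frac == 0.5 and cond

    def test_few_frames_flagged(self):
        cs = ps.find_clusters(np.array([[0, 0, 0], [1, 0, 0.0]]), 1.5)
        _, _, flagged = ps.is_condensed([cs], 2)
        assert flagged


class TestRadiusOfGyration:
    def test_single_bead(self):
        assert ps.radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_beads(self):
        pos = np.array([[0, 0, 0], [3.0, 0, 0]])
        assert ps.radius_of_gyration(pos) == pytest.approx(1.5)

    def test_matches_double_loop_formula(self, rng):
        pos = rng.normal(size=(100, 3))
        # Rg^2 = (1/2N^2) sum_ij |ri-rj|^2
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        expected = np.sqrt(d2.sum() / (2 * 100 ** 2))
        assert ps.radius_of_gyration(pos) == pytest.approx(expected, rel=1e-12)


class TestComDistance:
    def test_identical_sets(self, rng):
        pos = rng.normal(size=(20, 3)) * 0.3
        d, _ = ps.com_distance(pos, pos.copy())
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_two_single_beads(self):
        d, _ = ps.com_distance(np.array([[0, 0, 0.0]]), np.array([[1, 0, 0.0]]))
        assert d == pytest.approx(1.0)

    def test_concentric_shells(self):
        inner = dense_ball(3.0)
        outer = dense_shell(5.0, 7.0)
        d, _ = ps.com_distance(inner, outer)
        assert d == pytest.approx(0.0, abs=0.05)

    def test_uncondensed_flagged(self):
        spread = np.diag([5.0, 15.0, 25.0])
        _, flagged = ps.com_distance(spread, dense_ball(2.0))
        assert flagged


class TestSurfaceCoverage:
    def test_fully_surrounded_single_bead(self):
        f = np.zeros((1, 3))
        phi = np.pi * (1 + np.sqrt(5))
        k = np.arange(12)
        z = 1 - 2 * (k + 0.5) / 12
        r = np.sqrt(1 - z ** 2)
        x = np.stack([r * np.cos(phi * k), r * np.sin(phi * k), z], axis=1)
        cov, verdict = ps.surface_coverage(f, x)
        assert cov == 1.0 and verdict == "complete"

    def test_no_contact(self):
        cov, verdict = ps.surface_coverage(dense_ball(2.0),
                                           dense_ball(1.0, centre=(20, 0, 0)))
        assert cov == 0.0 and verdict == "none"

    def test_hemispherical_cap_is_partial(self):
        """X shell over the upper hemisphere covers ~half the surface beads."""
        f = packed_ball(4.0, seed=1)
        shell = packed_shell(4.4, 5.5, seed=2)
        x = shell[shell[:, 2] > 0]
        cov, verdict = ps.surface_coverage(f, x)
        # count oracle: surface beads (same coordination rule) whose nearest
        # cap bead is within the contact cutoff, via brute-force distances
        from pchsim.observables import _surface_mask
        surf = f[_surface_mask(f)]
        d = np.sqrt(((surf[:, None, :] - x[None, :, :]) ** 2).sum(-1)).min(1)
        expected = np.mean(d <= CLUSTER_CUTOFF)
        assert cov == pytest.approx(expected, abs=1e-12)
        assert 0.3 < cov < 0.7 and verdict == "partial"


class TestInteriorFraction:
    def test_all_at_centroid(self):
        f = dense_ball(4.0)
        rd = np.zeros((10, 3))
        assert ps.interior_fraction(rd, f) == 1.0

    def test_all_far_outside(self):
        f = dense_ball(4.0)
        rd = dense_ball(1.0, centre=(12.0, 0, 0))
        assert ps.interior_fraction(rd, f) == 0.0

    def test_half_split(self):
        f = dense_ball(4.0)
        rd = np.concatenate([np.zeros((50, 3)),
                             np.tile([20.0, 0, 0], (50, 1))])
        assert ps.interior_fraction(rd, f) == pytest.approx(0.5)


def _state_from_parts(h, rd, f, x, Rc=60.0):
    pos = np.concatenate([h, rd, f, x])
    species = np.concatenate([
        np.full(len(h), SPECIES_INDEX["H"]),
        np.full(len(rd), SPECIES_INDEX["rD"]),
        np.full(len(f), SPECIES_INDEX["F"]),
        np.full(len(x), SPECIES_INDEX["X"])]).astype(np.int8)
    return ps.SystemState(positions=pos, species=species, Rc=Rc)


def _layered_state():
    f = packed_ball(5.0, seed=3)
    x = packed_shell(5.2, 7.0, seed=4)
    h = packed_shell(7.2, 10.0, seed=5)
    rd = packed_ball(2.0, seed=6)
    return _state_from_parts(h, rd, f, x)


class TestLayeringVerdict:
    def test_concentric_shells_are_layered(self):
        rep = ps.layering_verdict(_layered_state())
        assert rep.verdict == "layered"
        assert rep.x_coverage_verdict == "complete"
        m = rep.radial_medians
        assert m["F"] < m["X"] < m["H"]

    def test_separated_balls_with_h_around_x(self):
        f = packed_ball(4.0, seed=7, centre=(30.0, 0, 0))
        x = packed_ball(4.0, seed=8)
        h = packed_shell(4.2, 7.0, seed=9)
        rd = packed_ball(1.5, seed=10, centre=(30.0, 0, 0))
        rep = ps.layering_verdict(_state_from_parts(h, rd, f, x))
        assert rep.verdict == "neocondensate_in_H"
        assert rep.d_HF > 0

    def test_random_mixture_is_not_layered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-8, 8, size=(800, 3))
        pts = pts[np.linalg.norm(pts, axis=1) < 8][:360]
        assert len(pts) == 360
        h, rd, f, x = np.split(pts, 4)
        rep = ps.layering_verdict(_state_from_parts(h, rd, f, x, Rc=20.0))
        assert rep.verdict != "layered"

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        st0 = _layered_state()
        R = Rotation.random(random_state=7).as_matrix()
        shift = np.array([3.0, -2.0, 5.0])
        st1 = ps.SystemState(positions=st0.positions @ R.T + shift,
                             species=st0.species, Rc=st0.Rc + 10)
        r0 = ps.layering_verdict(st0)
        r1 = ps.layering_verdict(st1)
        assert r0.verdict == r1.verdict
        assert r1.d_FX == pytest.approx(r0.d_FX, abs=1e-8)

    def test_missing_species_partial_report(self):
        f = dense_ball(4.0)
        h = dense_shell(5.0, 8.0)
        rep = ps.layering_verdict(_state_from_parts(h, np.zeros((0, 3)), f,
                                                    np.zeros((0, 3))))
        assert "X" in rep.absent_species
        assert rep.d_HF is not None and rep.d_FX is None
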