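"""Integrator correctness: determinism, thermostat, forces, confinement."""

import numpy as np
import pytest

import pchsim as ps
from pchsim.engine import SKIN
from pchsim.model import SPECIES, SPECIES_INDEX


def _random_mixed_system(n=200, Rc=7.0, n_poly=50, seed=0):
    """Polymer + free beads of all species in a small sphere."""
    topo = ps.build_topology(n_poly, 0.2, n_F=(n - n_poly) // 2,
                             n_X=n - n_poly - (n - n_poly) // 2)
    params = ps.SimulationParameters(Rc=Rc)
    state = ps.initialize_positions(topo, params, seed=seed)
    matrix = ps.InteractionMatrix()
    matrix.set_pair("F", "F", 2.0).set_pair("F", "X", 1.5)
    matrix.set_pair("X", "X", 1.75).set_pair("H", "H", 0.35)
    matrix.set_pair("X", "H", 1.0).set_pair("rD", "F", 2.0)
    return topo, params, state, matrix


def brute_force_reference(state, topo, matrix, params):
    """Independent all-pairs force oracle (pure numpy, no neighbour list)."""
    pos = state.positions
    n = len(pos)
    eps_tab, rc2_tab, _ = matrix.tables(params)
    species = topo.species.astype(int)
    f = np.zeros((n, 3))
    # pair forces with 1-2 exclusion
    bonded = {(int(i), int(j)) for i, j in topo.bonds}
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            d = pos[i] - pos[j]
            r2 = d @ d
            if r2 >= rc2_tab[species[i], species[j]]:
                continue
            e = eps_tab[species[i], species[j]]
            sr6 = r2 ** -3
            fr = 24 * e * (2 * sr6 * sr6 - sr6) / r2
            f[i] += fr * d
            f[j] -= fr * d
    for i, j in topo.bonds:
        d = pos[i] - pos[j]
        r = np.linalg.norm(d)
        fm = -2 * params.ks * (r - 1.0) / r
        f[i] += fm * d
        f[j] -= fm * d
    for i, j, k in topo.angles:
        a, b = pos[i] - pos[j], pos[k] - pos[j]
        la, lb = np.linalg.norm(a), np.linalg.norm(b)
        ct = np.clip(a @ b / (la * lb), -1, 1)
        fi = -params.k_bend * (b / (la * lb) - ct * a / la ** 2)
        fk = -params.k_bend * (a / (la * lb) - ct * b / lb ** 2)
        f[i] += fi
        f[k] += fk
        f[j] -= fi + fk
    for i in range(n):
        rr = np.linalg.norm(pos[i])
        d = params.Rc - rr
        if d < 2 ** (1 / 6):
            sr6 = d ** -6.0
            g = 24 * (2 * sr6 * sr6 - sr6) / d
            f[i] -= g * pos[i] / rr
    return f


class TestForces:
    def test_neighbour_list_matches_brute_force(self):
        topo, params, state, matrix = _random_mixed_system()
        # decorrelate from the lattice-free initial configuration
        ps.integrate(state, topo, params, matrix, 500, seed=9)
        forces, _ = ps.compute_forces(state, topo, matrix, params)
        ref = brute_force_reference(state, topo, matrix, params)
        scale = np.abs(ref).max()
        assert np.abs(forces - ref).max() <= 1e-9 * max(scale, 1.0)

    def test_empty_system(self):
        topo = ps.build_topology(0, 0.0)
        params = ps.SimulationParameters(Rc=5.0)
        state = ps.SystemState(positions=np.zeros((0, 3)),
                               species=topo.species, Rc=5.0)
        forces, pe = ps.compute_forces(state, topo, matrix=ps.InteractionMatrix(),
                                       params=params)
        assert forces.shape == (0, 3) and pe == 0.0

    def test_attraction_window(self):
        """Nonzero attraction at 2.4 sigma, none beyond the 2.5-sigma cutoff."""
        topo = ps.build_topology(0, 0.0, n_F=2)
        params = ps.SimulationParameters(Rc=20.0)
        matrix = ps.InteractionMatrix().set_pair("F", "F", 2.0)

        def force_at(r):
            st = ps.SystemState(positions=np.array([[0, 0, 0], [r, 0, 0.0]]),
                                species=topo.species, Rc=20.0)
            return ps.compute_forces(st, topo, matrix, params)[0]

        f_24 = force_at(2.4)
        assert f_24[0, 0] > 0  # pulled toward the partner: attractive
        assert np.allclose(force_at(2.6), 0.0)


class TestIntegration:
    def test_same_seed_bit_identical(self):
        topo, params, state, matrix = _random_mixed_system(n=80, n_poly=20)
        s2 = ps.SystemState(positions=state.positions.copy(),
                            species=state.species.copy(), Rc=params.Rc)
        s2.velocities = state.velocities.copy()
        t1 = ps.integrate(state, topo, params, matrix, 2000, seed=77)
        t2 = ps.integrate(s2, topo, params, matrix, 2000, seed=77)
        assert np.array_equal(t1.frames[-1], t2.frames[-1])

    def test_negligible_temperature_freezes_free_bead(self):
        """With no forces and vanishing thermal energy, positions hold still."""
        topo = ps.build_topology(0, 0.0, n_F=1)
        params = ps.SimulationParameters(Rc=50.0, kBT=1e-30)
        state = ps.SystemState(positions=np.array([[1.0, 2.0, 3.0]]),
                               species=topo.species, Rc=50.0)
        state.velocities = np.zeros((1, 3))
        traj = ps.integrate(state, topo, params, ps.InteractionMatrix(),
                            5000, seed=1)
        assert np.allclose(traj.frames[-1], [[1.0, 2.0, 3.0]], atol=1e-9)

    def test_kinetic_temperature_near_unity(self):
        topo, params, state, matrix = _random_mixed_system(n=150, n_poly=40)
        traj = ps.integrate(state, topo, params, matrix, 20_000, seed=4,
                            save_every=500)
        assert np.mean(traj.kinetic_temps[10:]) == pytest.approx(1.0, rel=0.05)

    def test_beads_stay_confined(self):
        topo, params, state, matrix = _random_mixed_system(n=120, n_poly=30)
        traj = ps.integrate(state, topo, params, matrix, 10_000, seed=6)
        r = np.linalg.norm(traj.frames.reshape(-1, 3), axis=1)
        assert r.max() <= params.Rc

    def test_neighbour_list_rebuilds_logged(self):
        topo, params, state, matrix = _random_mixed_system(n=100, n_poly=25)
        traj = ps.integrate(state, topo, params, matrix, 5000, seed=2)
        assert traj.provenance["n_rebuilds"] > 0

    def test_bond_length_statistics(self):
        """Equilibrium bond lengths: peak sigma, width (2 ks)^(-1/2)."""
        topo = ps.build_topology(50, 0.0)
        params = ps.SimulationParameters(Rc=12.0)
        state = ps.initialize_positions(topo, params, seed=8)
        matrix = ps.InteractionMatrix()
        traj = ps.integrate(state, topo, params, matrix, 40_000, seed=3,
                            save_every=1000)
        lens = []
        for fr in traj.frames[10:]:
            lens.extend(np.linalg.norm(np.diff(fr[:50], axis=0), axis=1))
        lens = np.asarray(lens)
        assert np.mean(lens) == pytest.approx(1.0, abs=0.02)
        assert np.std(lens) == pytest.approx((2 * 100) ** -0.5, rel=0.2)


class TestRunProtocol:
    def test_zero_production_returns_single_frame(self):
        topo = ps.build_topology(20, 0.2, n_F=10)
        params = ps.SimulationParameters(Rc=6.0)
        matrix = ps.InteractionMatrix().set_pair("F", "F", 1.0)
        traj, summary = ps.run_protocol(topo, params, matrix, seed=1,
                                        n_pushoff=200, n_equil=200,
                                        n_production=0)
        assert traj.n_frames == 1

    def test_replay_identical_summary(self):
        topo = ps.build_topology(20, 0.2, n_F=10)
        params = ps.SimulationParameters(Rc=6.0)
        matrix = ps.InteractionMatrix().set_pair("F", "F", 1.5)
        r1 = ps.run_protocol(topo, params, matrix, seed=5, n_pushoff=100,
                             n_equil=500, n_production=2000)
        r2 = ps.run_protocol(topo, params, matrix, seed=5, n_pushoff=100,
                             n_equil=500, n_production=2000)
        assert r1[1] == r2[1]
        assert np.array_equal(r1[0].frames[-1], r2[0].frames[-1])
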