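"""Langevin dynamics driver: trajectories, force evaluation, staged protocols.

The integrator is underdamped Langevin dynamics (BAOAB splitting of
velocity-Verlet with an exact Ornstein-Uhlenbeck friction/noise step),
holding the system at temperature kBT inside a repulsive spherical wall.
Identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import InteractionMatrix, SimulationParameters
from .topology import SystemState, Topology

__all__ = ["Trajectory", "integrate", "compute_forces", "run_protocol"]

#: neighbour-list skin (sigma); rebuilds trigger at half-skin displacement
SKIN = 0.6

_CODE_VERSION = "pchsim-0.1.0"


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time-ordered frames plus enough provenance to re-run bit-identically."""

    frames: np.ndarray            # (n_frames, n_beads, 3)
    times: np.ndarray             # reduced time per frame
    species: np.ndarray           # int8 codes, shared by all frames
    Rc: float
    save_every: int
    kinetic_temps: np.ndarray = field(default_factory=lambda: np.zeros(0))
    potential_energies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def final_state(self) -> SystemState:
        return SystemState(positions=self.frames[-1].copy(),
                           species=self.species.copy(), Rc=self.Rc,
                           time=float(self.times[-1]))


def _tables(matrix: InteractionMatrix, params: SimulationParameters):
    eps, rc2, vcut = matrix.tables(params)
    return (np.ascontiguousarray(eps), np.ascontiguousarray(rc2),
            np.ascontiguousarray(vcut))


def compute_forces(state: SystemState, topology: Topology,
                   matrix: InteractionMatrix, params: SimulationParameters):
    """Per-bead force vectors (bond + angle + pair + wall) and potential energy.

    Uses the same cell-list path as the integrator; equals a brute-force
    all-pairs evaluation exactly for pairs within the cutoff.
    """
    eps, rc2, vcut = _tables(matrix, params)
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    n = len(pos)
    species = topology.species.astype(np.int64)
    forces = np.zeros((n, 3))
    pairs = np.empty((n * 140 + 2048, 2), np.int32)
    rlist = params.rc_attr + SKIN
    npair = _kernels.build_pairs(pos, rlist * rlist, params.Rc, pairs)
    if npair < 0:
        raise IntegrationError("neighbour-list buffer overflow")
    pe, nclamp = _kernels.eval_forces(
        pos, species, eps, rc2, vcut,
        topology.bonds.astype(np.int64).reshape(-1, 2),
        topology.angles.astype(np.int64).reshape(-1, 3),
        params.ks, params.k_bend, params.Rc, pairs, npair, forces, True,
        topology.n_polymer)
    return forces, float(pe)


def integrate(state: SystemState, topology: Topology,
              params: SimulationParameters, matrix: InteractionMatrix,
              n_steps: int, seed: int, save_every: int = 0,
              fcap: float = 0.0) -> Trajectory:
    """Advance ``state`` by ``n_steps`` Langevin steps (mutates it in place).

    ``save_every=0`` picks ~50 frames.  ``fcap>0`` caps the per-bead force
    magnitude (soft push-off stage); capped evaluations are counted in the
    provenance block.
    """
    if params.dt > params.dt_max:
        raise IntegrationError("dt above stability bound; refusing to start")
    if save_every <= 0:
        save_every = max(1, n_steps // 50)
    eps, rc2, vcut = _tables(matrix, params)
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    vel = (np.ascontiguousarray(state.velocities, dtype=np.float64)
           if state.velocities is not None else np.zeros_like(pos))
    # the kernel mutates pos in place; keep a snapshot for frame 0
    pos0 = pos.copy()
    species = topology.species.astype(np.int64)
    nf = n_steps // save_every + (1 if n_steps % save_every else 0) + 1
    frames = np.empty((nf, len(pos), 3))
    frame_steps = np.zeros(nf, np.int64)
    temps = np.zeros(nf)
    pes = np.zeros(nf)

    nframe, nclamp, nrebuild, status = _kernels.langevin_run(
        pos, vel, species, eps, rc2, vcut,
        topology.bonds.astype(np.int64).reshape(-1, 2),
        topology.angles.astype(np.int64).reshape(-1, 3),
        params.ks, params.k_bend, params.Rc, params.kBT, params.gamma,
        params.mass, params.dt, int(n_steps), int(seed) & 0x7FFFFFFF,
        float(fcap), int(save_every), frames, frame_steps, temps, pes,
        SKIN, params.rc_attr, topology.n_polymer)
    if status == 2:
        raise IntegrationError("neighbour-list buffer overflow")
    if status == 1:
        raise IntegrationError(
            f"non-finite forces at frame {nframe}; last good frame retained")

    t0 = state.time
    all_frames = np.concatenate([pos0[None, :, :], frames[:nframe]])
    times = t0 + params.dt * np.concatenate([[0], frame_steps[:nframe]])
    state.positions = pos
    state.velocities = vel
    state.time = float(times[-1])
    return Trajectory(
        frames=all_frames, times=times, species=topology.species.copy(),
        Rc=params.Rc, save_every=save_every,
        kinetic_temps=temps[:nframe], potential_energies=pes[:nframe],
        provenance={
            "params": dataclasses.asdict(params),
            "matrix": matrix.to_dict(),
            "n_steps": int(n_steps), "seed": int(seed),
            "save_every": int(save_every), "fcap": float(fcap),
            "n_force_clamps": int(nclamp), "n_rebuilds": int(nrebuild),
            "code_version": _CODE_VERSION,
        })


def run_protocol(topology: Topology, params: SimulationParameters,
                 matrix: InteractionMatrix, seed: int,
                 n_pushoff: int = 2_000, n_equil: int = 20_000,
                 n_production: int = 100_000, save_every: int = 0,
                 initial_state: SystemState | None = None,
                 anneal_kBT: float = 0.0, n_anneal: int = 0,
                 anneal_stages: int = 4):
    """Staged run: capped-force push-off, (optional) annealing ramp,
    equilibration, then production.

    When ``anneal_kBT > params.kBT`` and ``n_anneal > 0``, the system is
    first evolved at elevated temperature, ramped down to ``params.kBT``
    over ``anneal_stages`` equal stages of ``n_anneal / anneal_stages``
    steps each.  Condensed phases at the reference attraction strengths sit
    below the Lennard-Jones triple point and barely rearrange from a random
    start; a short anneal lets the droplets wet and engulf as liquids
    before the organization is frozen in and classified.  Production always
    runs at ``params.kBT``.

    Returns ``(trajectory, summary)`` where the trajectory covers the
    production stage and the summary holds final-frame observables and the
    full provenance of the staged protocol.
    """
    from .model import SPECIES_INDEX
    from .observables import largest_cluster_fraction
    from .topology import initialize_positions

    state = initial_state or initialize_positions(topology, params, seed=seed)
    if n_pushoff > 0:
        integrate(state, topology, params, matrix, n_pushoff, seed=seed * 7 + 1,
                  fcap=20.0, save_every=max(1, n_pushoff))
    if anneal_kBT > params.kBT and n_anneal > 0:
        temps = np.linspace(anneal_kBT, params.kBT, anneal_stages + 1)[:-1]
        per_stage = max(1, n_anneal // anneal_stages)
        for k, kbt in enumerate(temps):
            integrate(state, topology, params.with_(kBT=float(kbt)),
                      matrix, per_stage, seed=seed * 7 + 100 + k,
                      save_every=per_stage)
    if n_equil > 0:
        integrate(state, topology, params, matrix, n_equil, seed=seed * 7 + 2,
                  save_every=max(1, n_equil // 5))
    if n_production > 0:
        traj = integrate(state, topology, params, matrix, n_production,
                         seed=seed * 7 + 3, save_every=save_every)
    else:
        # no production: a single-frame trajectory of the equilibrated state
        traj = Trajectory(
            frames=state.positions[None, :, :].copy(),
            times=np.array([state.time]), species=topology.species.copy(),
            Rc=params.Rc, save_every=1,
            provenance={"params": dataclasses.asdict(params),
                        "matrix": matrix.to_dict(), "n_steps": 0,
                        "seed": int(seed), "code_version": _CODE_VERSION})
    traj.provenance["protocol"] = {
        "seed": int(seed), "n_pushoff": n_pushoff, "n_equil": n_equil,
        "n_production": n_production, "anneal_kBT": anneal_kBT,
        "n_anneal": n_anneal,
    }
    summary = {
        "kinetic_temp_mean": float(np.mean(traj.kinetic_temps))
        if len(traj.kinetic_temps) else float("nan"),
        "potential_energy_final": float(traj.potential_energies[-1])
        if len(traj.potential_energies) else float("nan"),
        "largest_cluster_fraction": {
            name: largest_cluster_fraction(traj, name)
            for name in ("H", "rD", "F", "X")
            if np.any(traj.species == SPECIES_INDEX[name])
        },
    }
    return traj, summary
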