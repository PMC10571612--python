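"""Chain/protein topology construction and initial configurations.

The chromatin fibre is one bead-spring chain: two PCH (H) blocks flanking a
single contiguous rDNA (rD) block centred in the chain.  Fibrillarin (F)
and amphiphilic-protein (X) beads are free (unbonded) particles.  All beads
live inside a spherical confinement of radius ``Rc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .model import SPECIES, SPECIES_INDEX, InteractionMatrix, SimulationParameters

__all__ = ["Topology", "SystemState", "SystemSpec", "build_topology",
           "initialize_positions", "initialize_droplet_state", "scale_system"]


class CapacityError(ValueError):
    """Confinement too small for the requested bead count."""


@dataclass
class Topology:
    """Per-bead species labels plus bond/angle connectivity.

    ``species`` is an int8 array coding into :data:`pchsim.model.SPECIES`;
    ``bonds`` (M,2) links consecutive polymer beads only; ``angles`` (K,3)
    lists consecutive bonded triples.  ``h_blocks`` / ``rd_block`` are
    (start, stop) index ranges (stop exclusive) annotating the chain.
    """

    species: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    n_polymer: int
    h_blocks: tuple
    rd_block: tuple

    @property
    def n_beads(self) -> int:
        return len(self.species)

    def count(self, name: str) -> int:
        return int(np.sum(self.species == SPECIES_INDEX[name]))

    def species_names(self) -> np.ndarray:
        return np.asarray(SPECIES, dtype=object)[self.species]


@dataclass
class SystemState:
    """Bead positions + species inside the confinement sphere."""

    positions: np.ndarray
    species: np.ndarray
    Rc: float
    time: float = 0.0
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if len(self.positions) != len(self.species):
            raise ValueError("positions and species must have equal length")
        r = np.linalg.norm(self.positions, axis=1) if len(self.positions) else np.zeros(0)
        if len(r) and r.max() > self.Rc - 0.5 + 1e-9:
            raise ValueError(
                f"bead outside confinement: max |r|={r.max():.3f} > Rc-sigma/2={self.Rc - 0.5:.3f}"
            )


@dataclass(frozen=True)
class SystemSpec:
    """Complete specification of a simulated system (counts, box, matrix)."""

    n_pch: int = 10_000
    rdna_fraction: float = 0.2
    n_F: int = 4962
    n_X: int = 4962
    Rc: float = 45.0

    def with_(self, **kw) -> "SystemSpec":
        return replace(self, **kw)


def build_topology(n_pch: int, rdna_fraction: float = 0.2,
                   n_F: int = 0, n_X: int = 0) -> Topology:
    """Build the H/rD block copolymer plus free F and X beads.

    A central contiguous run of ``round(rdna_fraction * n_pch)`` chain beads
    is labelled rD; the flanks are H.  F and X beads are appended unbonded.
    """
    if not 0 <= rdna_fraction < 1:
        raise ValueError("rdna_fraction must lie in [0, 1)")
    if min(n_pch, n_F, n_X) < 0:
        raise ValueError("bead counts must be >= 0")
    n_rd = int(round(rdna_fraction * n_pch))
    start = (n_pch - n_rd) // 2
    species = np.empty(n_pch + n_F + n_X, dtype=np.int8)
    species[:n_pch] = SPECIES_INDEX["H"]
    species[start:start + n_rd] = SPECIES_INDEX["rD"]
    species[n_pch:n_pch + n_F] = SPECIES_INDEX["F"]
    species[n_pch + n_F:] = SPECIES_INDEX["X"]

    idx = np.arange(n_pch, dtype=np.int32)
    bonds = np.stack([idx[:-1], idx[1:]], axis=1) if n_pch >= 2 else np.zeros((0, 2), np.int32)
    angles = (np.stack([idx[:-2], idx[1:-1], idx[2:]], axis=1)
              if n_pch >= 3 else np.zeros((0, 3), np.int32))
    return Topology(
        species=species, bonds=bonds, angles=angles, n_polymer=n_pch,
        h_blocks=((0, start), (start + n_rd, n_pch)),
        rd_block=(start, start + n_rd),
    )


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def initialize_positions(topology: Topology, params: SimulationParameters,
                         seed: int = 0, min_dist: float = 0.8) -> SystemState:
    """Place the polymer as a confined self-avoiding walk and free beads uniformly.

    Deterministic for a given seed.  Guarantees every pair is at least
    ``min_dist`` sigma apart and every bead lies within ``Rc - sigma``.
    """
    rng = np.random.default_rng(seed)
    Rc = params.Rc
    rmax = Rc - 1.0
    n = topology.n_beads
    packing = n * (math.pi / 6.0) / ((4.0 / 3.0) * math.pi * Rc ** 3)
    if packing >= 0.5:
        raise CapacityError(
            f"{n} beads exceed packing 0.5 inside Rc={Rc} (packing={packing:.2f})")

    pos = np.zeros((n, 3))
    # coarse occupancy grid for O(1) proximity checks
    cell = max(min_dist, 1.0)
    occupied: dict[tuple, list[int]] = {}

    def key(p):
        return (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))

    def clashes(p, upto):
        k = key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in occupied.get((k[0] + dx, k[1] + dy, k[2] + dz), ()):
                        d = p - pos[j]
                        if d @ d < min_dist * min_dist:
                            return True
        return False

    def place(i, p):
        pos[i] = p
        occupied.setdefault(key(p), []).append(i)

    npoly = topology.n_polymer
    # polymer: self-avoiding random walk with unit bond length, restart on dead ends
    for attempt in range(200):
        start = _random_unit(rng) * (rmax * 0.5 * rng.random() ** (1 / 3))
        trial_ok = True
        occupied.clear()
        place(0, start) if npoly else None
        i = 1
        while i < npoly:
            for _ in range(60):
                p = pos[i - 1] + _random_unit(rng)
                if p @ p <= rmax * rmax and not clashes(p, i):
                    place(i, p)
                    break
            else:
                trial_ok = False
                break
            i += 1
        if trial_ok:
            break
    else:
        raise CapacityError("could not lay down polymer inside confinement")

    # free beads: uniform rejection sampling in the sphere
    for i in range(npoly, n):
        for _ in range(20_000):
            p = rng.uniform(-rmax, rmax, size=3)
            if p @ p <= rmax * rmax and not clashes(p, i):
                place(i, p)
                break
        else:
            raise CapacityError(f"could not place free bead {i} (limit {n})")

    state = SystemState(positions=pos, species=topology.species.copy(), Rc=Rc)
    state.velocities = np.zeros_like(pos)
    # sanity: the construction already enforces the minimum separation
    if n > 1:
        dmin = cKDTree(pos).query(pos, k=2)[0][:, 1].min()
        assert dmin >= min_dist - 1e-9
    return state


def initialize_droplet_state(topology: Topology, params: SimulationParameters,
                             seed: int = 0, droplet_fraction: float = 0.6,
                             droplet_density: float = 0.7,
                             min_dist: float = 0.95) -> SystemState:
    """Direct-coexistence initial condition: a compact droplet plus vapour.

    The first ``droplet_fraction`` of the beads are packed into a ball of
    number density ``droplet_density`` at the centre; the rest are placed
    uniformly outside it.  Used by the stability-based condensation calls:
    run at the working temperature, a state inside the binodal keeps the
    droplet, one outside evaporates it.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    n_drop = int(round(droplet_fraction * n))
    r_drop = (3.0 * n_drop / (4.0 * math.pi * droplet_density)) ** (1.0 / 3.0)
    rmax = params.Rc - 1.0
    if r_drop > rmax - 1.0:
        raise CapacityError("droplet does not fit the confinement")
    pos = np.zeros((n, 3))
    placed = 0
    md2 = min_dist * min_dist
    # rejection-packed ball (RSA at liquid-like density)
    for _ in range(200_000):
        if placed >= n_drop:
            break
        p = rng.uniform(-r_drop, r_drop, 3)
        if p @ p > r_drop * r_drop:
            continue
        d = pos[:placed] - p
        if placed and np.min(np.einsum("ij,ij->i", d, d)) < md2:
            continue
        pos[placed] = p
        placed += 1
    if placed < n_drop:
        raise CapacityError(
            f"could not pack droplet at density {droplet_density}")
    for i in range(n_drop, n):
        for _ in range(10_000):
            p = rng.uniform(-rmax, rmax, 3)
            r2 = p @ p
            if r2 > rmax * rmax or r2 < (r_drop + min_dist) ** 2:
                continue
            d = pos[n_drop:i] - p
            if i > n_drop and np.min(np.einsum("ij,ij->i", d, d)) < md2:
                continue
            pos[i] = p
            break
        else:
            raise CapacityError(f"could not place vapour bead {i}")
    state = SystemState(positions=pos, species=topology.species.copy(),
                        Rc=params.Rc)
    state.velocities = np.zeros_like(pos)
    return state


def scale_system(spec: SystemSpec, scale_factor: float, min_count: int = 10) -> SystemSpec:
    """Shrink a system spec preserving all number densities and epsilons.

    Bead counts scale by ``scale_factor`` (rounded); the confinement radius
    scales by ``scale_factor^(1/3)`` so concentrations are unchanged.
    """
    if not 0 < scale_factor <= 1:
        raise ValueError("scale_factor must lie in (0, 1]")
    if scale_factor == 1.0:
        return spec
    new = spec.with_(
        n_pch=int(round(spec.n_pch * scale_factor)),
        n_F=int(round(spec.n_F * scale_factor)),
        n_X=int(round(spec.n_X * scale_factor)),
        Rc=spec.Rc * scale_factor ** (1.0 / 3.0),
    )
    for name, n_orig, n_new in (("n_pch", spec.n_pch, new.n_pch),
                                ("n_F", spec.n_F, new.n_F),
                                ("n_X", spec.n_X, new.n_X)):
        if n_orig > 0 and n_new < min_count:
            raise ValueError(
                f"scale {scale_factor} leaves {name}={n_new} < {min_count}")
    return new
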