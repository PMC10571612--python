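"""Reduced units, energy terms and parameter calculators.

The model lives entirely in reduced units: the bead diameter ``sigma``
(~30 nm, ~5 kbp of chromatin) is the unit of length and the thermal energy
``kBT`` the unit of energy.  Four species are simulated: the
pericentromeric-heterochromatin polymer (H), the rDNA block embedded in it
(rD), and two diffusive protein species — Fibrillarin (F, nucleolar) and an
amphiphilic protein (X) with affinity for both nucleolar and PCH
components.  Pairwise interactions are truncated Lennard-Jones potentials;
pairs flagged ``excluded_volume`` interact purely repulsively (WCA form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "SPECIES",
    "SimulationParameters",
    "InteractionMatrix",
    "GenomeModel",
    "harmonic_bond",
    "lj_pair",
    "bending_energy",
    "confinement_radius_from_phi",
    "count_from_concentration",
    "concentration_from_count",
]

#: Species order used for integer coding throughout the package.
SPECIES = ("H", "rD", "F", "X")
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

_RC_REP = 2.0 ** (1.0 / 6.0)


class InvalidGeometryError(ValueError):
    """Raised for non-physical distances/angles passed to energy terms."""


@dataclass(frozen=True)
class SimulationParameters:
    """Physical constants and integrator settings in reduced units.

    Parameters
    ----------
    sigma : bead diameter, the length unit (= 1 in reduced units; one bead
        represents ~5 kbp of chromatin, ~30 nm).
    kBT : thermal energy, the energy unit.
    ks : bond spring constant, kBT/sigma^2.
    rc_attr : cutoff of attractive Lennard-Jones pairs (sigma).
    rc_rep : cutoff of excluded-volume (WCA) pairs; must equal 2^(1/6).
    Rc : confinement (nucleus) radius in sigma.
    dt : integration timestep in reduced time.
    gamma : Langevin friction coefficient (1/time).
    mass : bead mass.
    k_bend : bending stiffness of the chromatin chain (kBT); equals the
        persistence length in beads, 2 by default (60 nm).
    n_steps : default number of integration steps for a run.
    seed : RNG seed.
    """

    sigma: float = 1.0
    kBT: float = 1.0
    ks: float = 100.0
    rc_attr: float = 2.5
    rc_rep: float = _RC_REP
    Rc: float = 45.0
    dt: float = 0.005
    gamma: float = 1.0
    mass: float = 1.0
    k_bend: float = 2.0
    n_steps: int = 200_000
    seed: int = 0
    #: maximum dt accepted at construction (stability bound for ks=100).
    dt_max: float = 0.01

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")
        if not self.rc_rep < self.rc_attr:
            raise ValueError("rc_rep must be smaller than rc_attr")
        if abs(self.rc_rep - _RC_REP) > 1e-12:
            raise ValueError("rc_rep must equal 2^(1/6) sigma")
        if self.dt > self.dt_max:
            raise ValueError(
                f"dt={self.dt} exceeds the stability bound dt_max={self.dt_max}"
            )

    def with_(self, **kw) -> "SimulationParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class GenomeModel:
    """Genome coarse-graining: base pairs per bead and chromatin volume fraction.

    Defaults describe the diploid Drosophila genome (360 Mbp) at 5 kbp per
    bead with a chromatin volume fraction of 0.1.
    """

    genome_length_bp: float = 360e6
    bp_per_bead: float = 5e3
    phi: float = 0.1

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0 or self.bp_per_bead <= 0:
            raise ValueError("genome length and bp per bead must be positive")
        if not 0.0 < self.phi < 0.64:
            raise ValueError("phi must lie in (0, 0.64) (random close packing)")
        if (self.genome_length_bp / self.bp_per_bead) % 1.0 != 0.0:
            raise ValueError("genome_length_bp must be a multiple of bp_per_bead")

    @property
    def NG(self) -> int:
        """Total genome bead count."""
        return int(self.genome_length_bp / self.bp_per_bead)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    if a not in SPECIES_INDEX or b not in SPECIES_INDEX:
        raise KeyError(f"unknown species in pair ({a}, {b}); known: {SPECIES}")
    return (a, b) if SPECIES_INDEX[a] <= SPECIES_INDEX[b] else (b, a)


@dataclass
class InteractionMatrix:
    """Symmetric species-pair -> attraction-strength map.

    Each unordered pair of :data:`SPECIES` carries an attraction strength
    ``epsilon`` (kBT) and a mode: ``"attractive"`` pairs use the full LJ
    potential truncated at ``rc_attr``; ``"excluded_volume"`` pairs use the
    purely repulsive WCA form (epsilon forced to 1 kBT, cutoff ``rc_rep``).
    """

    pairs: dict = field(default_factory=dict)

    def set_pair(self, a: str, b: str, epsilon: float, mode: str = "attractive"):
        if mode not in ("attractive", "excluded_volume"):
            raise ValueError(f"unknown mode {mode!r}")
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        self.pairs[_pair_key(a, b)] = (float(epsilon), mode)
        return self

    def epsilon(self, a: str, b: str) -> float:
        eps, mode = self.pairs.get(_pair_key(a, b), (0.0, "excluded_volume"))
        return 1.0 if mode == "excluded_volume" else eps

    def mode(self, a: str, b: str) -> str:
        return self.pairs.get(_pair_key(a, b), (0.0, "excluded_volume"))[1]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            f"{a}-{b}": {"epsilon": eps, "mode": mode}
            for (a, b), (eps, mode) in sorted(
                self.pairs.items(),
                key=lambda kv: (SPECIES_INDEX[kv[0][0]], SPECIES_INDEX[kv[0][1]]),
            )
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionMatrix":
        m = cls()
        for key, val in d.items():
            a, b = key.split("-")
            m.set_pair(a, b, val["epsilon"], val["mode"])
        return m

    # -- tables for the integrator --------------------------------------
    def tables(self, params: SimulationParameters):
        """Dense (4,4) epsilon / squared-cutoff / energy-shift tables.

        The shift table holds the unshifted potential value at the pair's
        cutoff so that the evaluated energy is cut-and-shifted
        (``V(r) - V(rc)``), continuous at the cutoff.  Forces are unchanged.
        """
        n = len(SPECIES)
        eps = np.zeros((n, n))
        rc2 = np.zeros((n, n))
        vcut = np.zeros((n, n))
        for i, a in enumerate(SPECIES):
            for j, b in enumerate(SPECIES):
                e, mode = self.epsilon(a, b), self.mode(a, b)
                rc = params.rc_attr if mode == "attractive" else params.rc_rep
                eps[i, j] = e
                rc2[i, j] = rc * rc
                sr6 = rc ** -6
                vcut[i, j] = 4.0 * e * (sr6 * sr6 - sr6)
        return eps, rc2, vcut


# ---------------------------------------------------------------------------
# energy / force terms (scalar reference implementations; the integrator uses
# compiled equivalents in _kernels.py, tested against these)
# ---------------------------------------------------------------------------

def harmonic_bond(r: float, ks: float = 100.0, sigma: float = 1.0):
    """Bond energy ``ks (r - sigma)^2`` and scalar force ``-dV/dr``."""
    if r <= 0:
        raise InvalidGeometryError(f"bond length must be positive, got {r}")
    dr = r - sigma
    return ks * dr * dr, -2.0 * ks * dr


def lj_pair(
    r: float,
    epsilon: float,
    mode: str = "attractive",
    params: SimulationParameters | None = None,
    shifted: bool = True,
):
    """Truncated 12-6 Lennard-Jones energy (kBT) and scalar force ``-dV/dr``.

    ``attractive`` pairs are truncated at ``rc_attr`` (2.5 sigma);
    ``excluded_volume`` pairs evaluate the WCA form with epsilon=1 truncated
    at 2^(1/6) sigma.  With ``shifted=True`` (default) the energy is offset
    by ``V(rc)`` so it vanishes continuously at the cutoff; forces are
    identical either way.
    """
    if r <= 0:
        raise InvalidGeometryError(f"pair distance must be positive, got {r}")
    p = params or SimulationParameters()
    if mode == "attractive":
        rc, eps = p.rc_attr, epsilon
    elif mode == "excluded_volume":
        rc, eps = p.rc_rep, 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if r > rc:
        return 0.0, 0.0
    sr6 = (p.sigma / r) ** 6
    energy = 4.0 * eps * (sr6 * sr6 - sr6)
    force = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    if shifted:
        c6 = (p.sigma / rc) ** 6
        energy -= 4.0 * eps * (c6 * c6 - c6)
    return energy, force


def bending_energy(theta: float, k_bend: float = 2.0) -> float:
    """Bending energy ``k_bend (1 + cos theta)`` of a bonded bead triple.

    ``theta`` is the angle at the middle bead; a straight chain has
    ``theta = pi`` and zero energy.  ``k_bend = lp/sigma`` reproduces a
    persistence length ``lp`` (2 beads = 60 nm by default).
    """
    if not 0.0 <= theta <= math.pi + 1e-12:
        raise InvalidGeometryError(f"theta must lie in [0, pi], got {theta}")
    return k_bend * (1.0 + math.cos(theta))


# ---------------------------------------------------------------------------
# parameter calculators
# ---------------------------------------------------------------------------

def confinement_radius_from_phi(genome: GenomeModel, sigma: float = 1.0) -> float:
    """Confinement radius (sigma) from the chromatin volume fraction.

    phi = NG * (4/3) pi (sigma/2)^3 / ((4/3) pi Rc^3), i.e. beads of radius
    sigma/2, which gives ``Rc = (NG / (8 phi))^(1/3) sigma`` — 44.8 sigma
    (rounding to 45) for the 72,000-bead diploid genome at phi = 0.1.
    """
    if genome.phi <= 0:
        raise ValueError("phi must be positive")
    return (genome.NG / (8.0 * genome.phi)) ** (1.0 / 3.0) * sigma


def count_from_concentration(c: float, Rc: float) -> int:
    """Bead count from a number density ``c`` (sigma^-3) in a sphere of radius Rc."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return int(round(c * (4.0 / 3.0) * math.pi * Rc ** 3))


def concentration_from_count(n: int, Rc: float) -> float:
    """Inverse of :func:`count_from_concentration` (exact up to rounding)."""
    return n / ((4.0 / 3.0) * math.pi * Rc ** 3)
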