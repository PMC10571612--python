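"""Trajectory observables: clusters, condensation calls, radii of gyration,
inter-phase distances and wetting/engulfment/layering classifications.

"Condensed" is operationalised as the largest connected cluster (link
distance 1.5 sigma, the first coordination shell) holding at least half of a
species' beads, sustained over the final three saved frames.  Layering of
the three phases (H around X around F) is read off radial medians about the
Fibrillarin cluster centre together with the X-on-F surface coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .model import SPECIES, SPECIES_INDEX
from .topology import SystemState

__all__ = [
    "ClusterSet", "OrganizationReport", "find_clusters", "is_condensed",
    "largest_cluster_fraction", "radius_of_gyration", "com_distance",
    "surface_coverage", "interior_fraction", "layering_verdict",
]

#: default cluster link distance / contact cutoff (first coordination shell)
CLUSTER_CUTOFF = 1.5
#: largest-cluster fraction at or above which a species counts as condensed
CONDENSED_FRACTION = 0.5
#: surface-coverage thresholds separating none / partial / complete wetting
COVERAGE_NONE, COVERAGE_COMPLETE = 0.1, 0.75
#: F beads with fewer than this many same-species neighbours are "surface"
SURFACE_COORDINATION = 8


@dataclass
class ClusterSet:
    """Connected-component clustering of one species' beads."""

    labels: np.ndarray          # per-bead cluster label (dense from 0)
    indices: np.ndarray         # indices of the clustered beads in the parent set
    sizes: np.ndarray           # per-cluster bead count

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def largest_label(self) -> int:
        return int(np.argmax(self.sizes)) if len(self.sizes) else -1

    def largest_fraction(self) -> float:
        tot = self.sizes.sum()
        return float(self.sizes.max() / tot) if tot else 0.0

    def members(self, label: int) -> np.ndarray:
        return self.indices[self.labels == label]


def find_clusters(positions: np.ndarray, cutoff: float = CLUSTER_CUTOFF,
                  indices: np.ndarray | None = None) -> ClusterSet:
    """Connected components of the graph linking beads within ``cutoff``.

    Labels are deterministic: clusters are renumbered by their lowest member
    index.  An empty input yields an empty ClusterSet.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if indices is None:
        indices = np.arange(n)
    if n == 0:
        return ClusterSet(labels=np.zeros(0, int), indices=np.asarray(indices),
                          sizes=np.zeros(0, int))
    pairs = cKDTree(positions).query_pairs(cutoff, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, raw = sparse.csgraph.connected_components(graph, directed=False)
    # renumber by lowest member index so labelling is order-independent
    first = np.full(raw.max() + 1, n, int)
    np.minimum.at(first, raw, np.arange(n))
    order = np.argsort(first)
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[raw]
    sizes = np.bincount(labels)
    return ClusterSet(labels=labels, indices=np.asarray(indices), sizes=sizes)


def is_condensed(cluster_sets, n_species: int):
    """Condensation call from the final saved frames.

    ``cluster_sets`` is a ClusterSet or a sequence of them (one per frame,
    newest last); condensed means the largest-cluster fraction is at least
    :data:`CONDENSED_FRACTION` in each of the last three frames (boundary
    inclusive).  Returns ``(condensed, fraction_of_last_frame, flagged)``
    where ``flagged`` notes fewer than three frames were available.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if isinstance(cluster_sets, ClusterSet):
        cluster_sets = [cluster_sets]
    tail = list(cluster_sets)[-3:]
    fracs = [cs.largest_fraction() for cs in tail]
    condensed = bool(fracs) and all(f >= CONDENSED_FRACTION for f in fracs)
    return condensed, (fracs[-1] if fracs else 0.0), len(tail) < 3


def largest_cluster_fraction(traj, species_name: str,
                             cutoff: float = CLUSTER_CUTOFF) -> float:
    """Largest-cluster fraction of one species in the final frame."""
    sel = traj.species == SPECIES_INDEX[species_name]
    if not np.any(sel):
        return 0.0
    return find_clusters(traj.frames[-1][sel], cutoff).largest_fraction()


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance of beads from their centroid."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        raise ValueError("radius_of_gyration of an empty subset")
    d = positions - positions.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def _largest_cluster_positions(positions, cutoff=CLUSTER_CUTOFF):
    """Positions of the largest cluster, plus a flag if nothing condensed.

    When the species is entirely uncondensed (largest fraction below the
    condensation threshold) the full bead set is returned, flagged.
    """
    cs = find_clusters(positions, cutoff)
    if cs.n_clusters == 0:
        return positions, True
    if cs.largest_fraction() < CONDENSED_FRACTION:
        return positions, True
    mem = cs.labels == cs.largest_label
    return positions[mem], False


def com_distance(pos_a: np.ndarray, pos_b: np.ndarray,
                 cutoff: float = CLUSTER_CUTOFF):
    """Distance between the centres of mass of two species' largest clusters.

    Returns ``(distance, flagged)``; flagged is True when either species was
    uncondensed so all of its beads were used instead of a cluster.
    """
    a, fa = _largest_cluster_positions(np.asarray(pos_a, float), cutoff)
    b, fb = _largest_cluster_positions(np.asarray(pos_b, float), cutoff)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("com_distance requires non-empty bead sets")
    d = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    return d, (fa or fb)


def _surface_mask(cluster_pos, cutoff=CLUSTER_CUTOFF):
    tree = cKDTree(cluster_pos)
    # neighbour count excludes the bead itself
    counts = np.array(tree.query_ball_point(cluster_pos, cutoff,
                                            return_length=True)) - 1
    mask = counts < SURFACE_COORDINATION
    if not mask.any():
        # degenerate packing (denser than an LJ liquid): fall back to the
        # radially outermost quintile about the cluster centre
        r = np.linalg.norm(cluster_pos - cluster_pos.mean(axis=0), axis=1)
        mask = r >= np.percentile(r, 80)
    return mask


def surface_coverage(f_cluster_pos: np.ndarray, x_positions: np.ndarray,
                     contact_cutoff: float = CLUSTER_CUTOFF):
    """Fraction of the F-cluster surface wetted by X beads, with a verdict.

    Surface beads are F beads with fewer than 8 F neighbours within
    1.5 sigma; a surface bead is covered when at least one X bead lies
    within ``contact_cutoff``.  Verdict: none (<0.1), complete (>=0.75),
    else partial.
    """
    f_cluster_pos = np.asarray(f_cluster_pos, float)
    if len(f_cluster_pos) == 0:
        raise ValueError("surface_coverage requires a non-empty F cluster")
    x_positions = np.asarray(x_positions, float).reshape(-1, 3)
    surface = f_cluster_pos[_surface_mask(f_cluster_pos, contact_cutoff)]
    if len(x_positions) == 0 or len(surface) == 0:
        return 0.0, "none"
    d, _ = cKDTree(x_positions).query(surface, k=1)
    coverage = float(np.mean(d <= contact_cutoff))
    if coverage < COVERAGE_NONE:
        verdict = "none"
    elif coverage >= COVERAGE_COMPLETE:
        verdict = "complete"
    else:
        verdict = "partial"
    return coverage, verdict


def _radial_extent(cluster_pos, q=80):
    com = cluster_pos.mean(axis=0)
    return float(np.percentile(np.linalg.norm(cluster_pos - com, axis=1), q))


def interior_fraction(rd_positions: np.ndarray, f_cluster_pos: np.ndarray) -> float:
    """Fraction of rDNA beads inside the Fibrillarin cluster.

    "Inside" means closer to the F-cluster centre of mass than the cluster's
    80th-percentile radial extent.  Interior condensation is called at
    fraction >= 0.5, wrapping below.
    """
    f_cluster_pos = np.asarray(f_cluster_pos, float)
    rd_positions = np.asarray(rd_positions, float).reshape(-1, 3)
    if len(f_cluster_pos) == 0:
        raise ValueError("interior_fraction requires a non-empty F cluster")
    if len(rd_positions) == 0:
        return 0.0
    com = f_cluster_pos.mean(axis=0)
    extent = _radial_extent(f_cluster_pos)
    d = np.linalg.norm(rd_positions - com, axis=1)
    return float(np.mean(d < extent))


@dataclass
class OrganizationReport:
    """Classification of one configuration's multiphase organization."""

    verdict: str = "none"       # layered | partial_wetting | dissociated |
                                # neocondensate_in_H | none
    condensed: dict = field(default_factory=dict)
    d_HF: float | None = None
    d_FX: float | None = None
    rd_interior_fraction: float | None = None
    x_coverage_of_F: float | None = None
    x_coverage_verdict: str | None = None
    radial_medians: dict = field(default_factory=dict)
    absent_species: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def layering_verdict(state: SystemState,
                     cutoff: float = CLUSTER_CUTOFF) -> OrganizationReport:
    """Classify the organization of a full H/rD/F/X configuration.

    layered: radial medians about the F-cluster centre obey
    median_F < median_X < median_H and X completely wets F.
    neocondensate_in_H: F and X are dissociated, the X cluster sits inside
    the H condensate and F lies farther from H than X does.
    dissociated: F-X centre distance exceeds the sum of radial extents.
    """
    rep = OrganizationReport()
    pos, spec = state.positions, np.asarray(state.species)
    subsets = {name: pos[spec == SPECIES_INDEX[name]] for name in SPECIES}
    rep.absent_species = [s for s in SPECIES if len(subsets[s]) == 0]

    for name in SPECIES:
        if name in rep.absent_species:
            continue
        cs = find_clusters(subsets[name], cutoff)
        rep.condensed[name] = bool(cs.largest_fraction() >= CONDENSED_FRACTION)

    have = lambda *names: all(n not in rep.absent_species for n in names)
    clusters = {}
    for name in ("H", "F", "X"):
        if have(name):
            cpos, flagged = _largest_cluster_positions(subsets[name], cutoff)
            clusters[name] = cpos
            if flagged:
                rep.flags.append(f"{name}_uncondensed_all_beads_used")

    if have("F", "H"):
        rep.d_HF = com_distance(subsets["H"], subsets["F"], cutoff)[0]
    if have("F", "X"):
        rep.d_FX = com_distance(subsets["F"], subsets["X"], cutoff)[0]
    if have("F") and len(subsets["rD"]):
        rep.rd_interior_fraction = interior_fraction(subsets["rD"], clusters["F"])
    if have("F", "X"):
        rep.x_coverage_of_F, rep.x_coverage_verdict = surface_coverage(
            clusters["F"], subsets["X"], cutoff)

    if not have("F", "X", "H"):
        return rep

    f_com = clusters["F"].mean(axis=0)
    x_com = clusters["X"].mean(axis=0)
    h_com = clusters["H"].mean(axis=0)
    # radial medians about the F centre (X centre if F is dissociated from X)
    dissociated = rep.d_FX > _radial_extent(clusters["F"]) + _radial_extent(clusters["X"])
    centre = x_com if dissociated else f_com
    for name in ("F", "X", "H"):
        rep.radial_medians[name] = float(np.median(
            np.linalg.norm(subsets[name] - centre, axis=1)))

    if dissociated:
        h_extent = _radial_extent(clusters["H"])
        x_in_h = np.linalg.norm(x_com - h_com) < h_extent
        f_farther = (np.linalg.norm(f_com - h_com) > np.linalg.norm(x_com - h_com))
        rep.verdict = "neocondensate_in_H" if (x_in_h and f_farther) else "dissociated"
        return rep

    m = rep.radial_medians
    if m["F"] < m["X"] < m["H"] and rep.x_coverage_verdict == "complete":
        rep.verdict = "layered"
    elif rep.x_coverage_verdict == "partial":
        rep.verdict = "partial_wetting"
    else:
        rep.verdict = "none"
    return rep
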