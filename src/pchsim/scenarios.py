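"""Named simulation experiments and parameter sweeps.

Encodes the interaction-hierarchy scenarios (+rDNA and −rDNA), the
single-component Fibrillarin condensation phase diagram, the PCH collapse
sweep, the rDNA engulfment sweep, the X-on-F wetting sweep and the
amphiphile-depletion series.  Every sweep cell runs the staged Langevin
protocol and is classified with the observables module; results collect
into :class:`SweepResult`.

The reference (+rDNA) interaction hierarchy is
rD-F = F-F > X-X > F-X > X-H > H-H, with every other pair excluded-volume
only.  Default strengths (kBT): F-F = rD-F = 2.0, X-X = 1.75, F-X = 1.5,
X-H = 1.0, H-H = 0.35.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .engine import run_protocol
from .model import (InteractionMatrix, SimulationParameters,
                    count_from_concentration)
from .observables import (CLUSTER_CUTOFF, find_clusters, interior_fraction,
                          is_condensed, layering_verdict, radius_of_gyration,
                          _largest_cluster_positions, _surface_mask)
from .topology import SystemSpec, build_topology, initialize_positions, scale_system

__all__ = [
    "SweepResult", "plus_rdna_matrix", "minus_rdna_matrix", "run_scenario",
    "fibrillarin_phase_diagram", "pch_collapse_sweep", "rdna_engulfment_sweep",
    "wetting_sweep", "amphiphile_depletion_series", "FULL_SPEC", "DESK_SCALE",
]

#: full-size system: 10,000-bead chain, proteins at c = 0.013 in Rc = 45
FULL_SPEC = SystemSpec(n_pch=10_000, rdna_fraction=0.2,
                       n_F=4962, n_X=4962, Rc=45.0)
#: default desk-scale preset
DESK_SCALE = 1.0 / 8.0

_PLUS_RDNA_EPS = {("F", "F"): 2.0, ("rD", "F"): 2.0, ("X", "X"): 1.75,
                  ("F", "X"): 1.5, ("X", "H"): 1.0, ("H", "H"): 0.35}


class HierarchyError(ValueError):
    """An interaction override violates the affinity hierarchy."""


@dataclass
class SweepResult:
    """Grid axes, per-cell classifications and derived per-axis thresholds."""

    axes: dict = field(default_factory=dict)
    cells: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells)

    def to_dict(self) -> dict:
        return {"axes": self.axes, "cells": self.cells,
                "thresholds": self.thresholds, "flags": self.flags}


def _build_matrix(eps: dict, excluded=()) -> InteractionMatrix:
    m = InteractionMatrix()
    for (a, b), e in eps.items():
        m.set_pair(a, b, e, "attractive")
    for a, b in excluded:
        m.set_pair(a, b, 0.0, "excluded_volume")
    return m


def plus_rdna_matrix(**overrides) -> InteractionMatrix:
    """The +rDNA interaction matrix (strict hierarchy asserted).

    Overrides are keyword pairs like ``FF=2.0, rDF=2.0, XX=1.75, FX=1.5,
    XH=1.0, HH=0.35``.  Any override breaking
    rD-F = F-F > X-X > F-X > X-H > H-H raises :class:`HierarchyError`
    naming the violated inequality.
    """
    key = {"FF": ("F", "F"), "rDF": ("rD", "F"), "XX": ("X", "X"),
           ("FX"): ("F", "X"), "XH": ("X", "H"), "HH": ("H", "H")}
    eps = dict(_PLUS_RDNA_EPS)
    for name, val in overrides.items():
        if name not in key:
            raise KeyError(f"unknown pair override {name!r}")
        eps[key[name]] = float(val)
    e = {n: eps[k] for n, k in key.items()}
    checks = [("rD-F == F-F", e["rDF"] == e["FF"]),
              ("F-F > X-X", e["FF"] > e["XX"]),
              ("X-X > F-X", e["XX"] > e["FX"]),
              ("F-X > X-H", e["FX"] > e["XH"]),
              ("X-H > H-H", e["XH"] > e["HH"])]
    for name, ok in checks:
        if not ok:
            raise HierarchyError(f"hierarchy violated: {name} does not hold")
    return _build_matrix(eps, excluded=[("H", "F"), ("H", "rD"),
                                        ("rD", "rD"), ("rD", "X")])


def minus_rdna_matrix(x_h: float = 1.5) -> InteractionMatrix:
    """The −rDNA matrix: rD-F attraction removed, X-H raised to ``x_h``.

    The neocondensate-in-void regime needs X-H >= F-X; a weaker ``x_h``
    is accepted but warned about.
    """
    eps = dict(_PLUS_RDNA_EPS)
    del eps[("rD", "F")]
    eps[("X", "H")] = float(x_h)
    if x_h < eps[("F", "X")]:
        warnings.warn(
            f"x_h={x_h} < F-X={eps[('F', 'X')]}: outside the neocondensate "
            "regime (requires X-H >= F-X)", stacklevel=2)
    return _build_matrix(eps, excluded=[("H", "F"), ("H", "rD"),
                                        ("rD", "rD"), ("rD", "X"),
                                        ("rD", "F")])


def _run_cell(spec: SystemSpec, matrix: InteractionMatrix, seed: int,
              n_equil: int, n_production: int,
              params: SimulationParameters | None = None,
              anneal_kBT: float = 0.0, n_anneal: int = 0,
              anneal_stages: int = 4):
    topo = build_topology(spec.n_pch, spec.rdna_fraction, spec.n_F, spec.n_X)
    p = (params or SimulationParameters()).with_(Rc=spec.Rc)
    traj, summary = run_protocol(topo, p, matrix, seed=seed,
                                 n_equil=n_equil, n_production=n_production,
                                 save_every=max(1, n_production // 12),
                                 anneal_kBT=anneal_kBT, n_anneal=n_anneal,
                                 anneal_stages=anneal_stages)
    return traj, summary


def run_scenario(kind: str, scale: float = DESK_SCALE, seed: int = 1,
                 n_equil: int = 50_000, n_production: int = 200_000,
                 spec: SystemSpec | None = None, x_h: float = 1.5):
    """Run a named scenario ('plus-rdna' or 'minus-rdna') at a given scale.

    Returns ``(trajectory, OrganizationReport, summary)``.
    """
    if kind == "plus-rdna":
        matrix = plus_rdna_matrix()
    elif kind == "minus-rdna":
        matrix = minus_rdna_matrix(x_h=x_h)
    else:
        raise ValueError(f"unknown scenario {kind!r}")
    sp = scale_system(spec or FULL_SPEC, scale)
    traj, summary = _run_cell(sp, matrix, seed, n_equil, n_production)
    report = layering_verdict(traj.final_state())
    return traj, report, summary


def _condensed_from_traj(traj, n_species: int):
    tail = [find_clusters(f) for f in traj.frames[-3:]]
    return is_condensed(tail, n_species)


def fibrillarin_phase_diagram(c_grid, eps_grid, seeds=(1, 2, 3),
                              scale: float = DESK_SCALE,
                              n_equil: int = 20_000,
                              n_production: int = 150_000,
                              init: str = "droplet") -> SweepResult:
    """Condensation phase diagram of a single-component Fibrillarin system.

    For each concentration the threshold is the smallest attraction strength
    at which at least half the seeds condense; thresholds should be
    non-increasing in concentration (violations are flagged, not smoothed).
    ``init="droplet"`` (default) starts each cell from a preformed droplet
    plus vapour, so the condensed call measures phase stability;
    ``init="random"`` starts from a uniform gas and additionally requires
    nucleation within the run.
    """
    from .topology import initialize_droplet_state, initialize_positions
    c_grid, eps_grid = list(c_grid), list(eps_grid)
    if not c_grid or not eps_grid:
        raise ValueError("grids must be non-empty")
    if init not in ("droplet", "random"):
        raise ValueError(f"unknown init {init!r}")
    Rc = FULL_SPEC.Rc * scale ** (1.0 / 3.0)
    res = SweepResult(axes={"c_F": c_grid, "eps_FF": sorted(eps_grid),
                            "seeds": list(seeds), "init": init})
    for c in c_grid:
        n_f = count_from_concentration(c, Rc)
        for eps in sorted(eps_grid):
            m = InteractionMatrix().set_pair("F", "F", eps) if eps > 0 else \
                InteractionMatrix().set_pair("F", "F", 0.0, "excluded_volume")
            for seed in seeds:
                topo = build_topology(0, 0.0, n_f, 0)
                p = SimulationParameters(Rc=Rc)
                make = (initialize_droplet_state if init == "droplet"
                        else initialize_positions)
                state = make(topo, p, seed=seed)
                traj, _ = run_protocol(
                    topo, p, m, seed=seed, n_pushoff=1000, n_equil=n_equil,
                    n_production=n_production, initial_state=state,
                    save_every=max(1, n_production // 12))
                cond, frac, flagged = _condensed_from_traj(traj, n_f)
                res.cells.append({"c_F": c, "eps_FF": eps, "seed": seed,
                                  "n_F": n_f, "condensed": cond,
                                  "largest_fraction": frac})
    df = res.to_dataframe()
    thresholds = {}
    for c in c_grid:
        sub = df[df.c_F == c].groupby("eps_FF")["condensed"].mean()
        hit = sub[sub >= 0.5]
        thresholds[c] = float(hit.index.min()) if len(hit) else float("nan")
        # flag non-monotone condensation columns (undersampling signature)
        col = (sub >= 0.5).astype(int).values
        if np.any(np.diff(col) < 0):
            res.flags.append(f"non-monotone condensation column at c_F={c}")
    res.thresholds = {"condensation_eps_by_concentration": thresholds}
    vals = [thresholds[c] for c in sorted(c_grid)]
    if any(b > a + 1e-9 for a, b in zip(vals, vals[1:]) if not (np.isnan(a) or np.isnan(b))):
        res.flags.append("thresholds increase with concentration (undersampled)")
    return res


def pch_collapse_sweep(eps_hh_grid, chain_n: int = 400, seeds=(1, 2, 3),
                       n_equil: int = 50_000, n_production: int = 150_000,
                       Rc: float | None = None) -> SweepResult:
    """Coil-globule collapse of an isolated PCH chain vs self-attraction.

    A chain is collapsed when its production-averaged radius of gyration
    falls below 0.6x the athermal (eps_HH = 0) reference of the same chain.
    By default the confinement is weak (well beyond the athermal coil
    size), so the reference is a genuine self-avoiding coil rather than a
    wall-compressed one.
    """
    eps_hh_grid = sorted(eps_hh_grid)
    if Rc is None:
        Rc = 1.25 * chain_n ** 0.6
    res = SweepResult(axes={"eps_HH": eps_hh_grid, "seeds": list(seeds),
                            "chain_n": chain_n, "Rc": Rc})

    def mean_rg(eps, seed):
        m = (InteractionMatrix().set_pair("H", "H", eps) if eps > 0 else
             InteractionMatrix().set_pair("H", "H", 0.0, "excluded_volume"))
        spec = SystemSpec(n_pch=chain_n, rdna_fraction=0.0, n_F=0, n_X=0, Rc=Rc)
        traj, _ = _run_cell(spec, m, seed, n_equil, n_production)
        half = traj.frames[len(traj.frames) // 2:]
        return float(np.mean([radius_of_gyration(f) for f in half]))

    rg0 = float(np.mean([mean_rg(0.0, s) for s in seeds]))
    res.thresholds["rg_reference"] = rg0
    for eps in eps_hh_grid:
        for seed in seeds:
            rg = rg0 if eps == 0.0 else mean_rg(eps, seed)
            res.cells.append({"eps_HH": eps, "seed": seed, "rg": rg,
                              "collapsed": bool(rg < 0.6 * rg0)})
    df = res.to_dataframe()
    coll = df.groupby("eps_HH")["collapsed"].mean() >= 0.5
    onset = coll[coll].index.min() if coll.any() else float("nan")
    res.thresholds["collapse_onset_eps"] = float(onset)
    return res


def _rd_contact_fraction(rd_pos, f_cluster_pos, cutoff=CLUSTER_CUTOFF):
    if len(rd_pos) == 0 or len(f_cluster_pos) == 0:
        return 0.0
    d, _ = cKDTree(f_cluster_pos).query(rd_pos, k=1)
    return float(np.mean(d <= cutoff))


def rdna_engulfment_sweep(eps_rdf_values, seeds=(1, 2, 3),
                          scale: float = DESK_SCALE,
                          n_equil: int = 30_000,
                          n_production: int = 150_000) -> SweepResult:
    """Interior condensation vs wrapping of rDNA on the Fibrillarin phase.

    Three-component H/rD/F system with eps_HH = 0.35 and eps_FF = 2; the
    rDNA-Fibrillarin attraction is swept.  Classification: ``interior`` when
    at least half the rDNA beads lie inside the F cluster's 80th-percentile
    radius, ``wrapping`` when outside but in surface contact, else
    ``unassociated``.
    """
    sp = scale_system(FULL_SPEC.with_(n_X=0), scale)
    res = SweepResult(axes={"eps_rDF": list(eps_rdf_values), "seeds": list(seeds)})
    for eps in eps_rdf_values:
        eps_map = {("F", "F"): 2.0, ("H", "H"): 0.35}
        excl = [("H", "F"), ("H", "rD"), ("rD", "rD")]
        if eps > 0:
            eps_map[("rD", "F")] = eps
        else:
            excl.append(("rD", "F"))
        m = _build_matrix(eps_map, excluded=excl)
        for seed in seeds:
            traj, _ = _run_cell(sp, m, seed, n_equil, n_production)
            st = traj.final_state()
            from .model import SPECIES_INDEX
            f_pos = st.positions[st.species == SPECIES_INDEX["F"]]
            rd_pos = st.positions[st.species == SPECIES_INDEX["rD"]]
            f_cs = find_clusters(f_pos)
            cell = {"eps_rDF": eps, "seed": seed}
            if f_cs.largest_fraction() < 0.5:
                cell.update({"valid": False, "classification": "invalid"})
                res.cells.append(cell)
                continue
            f_cluster = f_pos[f_cs.labels == f_cs.largest_label]
            frac = interior_fraction(rd_pos, f_cluster)
            contact = _rd_contact_fraction(rd_pos, f_cluster)
            if frac >= 0.5:
                cls = "interior"
            elif contact >= 0.25:
                cls = "wrapping"
            else:
                cls = "unassociated"
            cell.update({"valid": True, "interior_fraction": frac,
                         "contact_fraction": contact, "classification": cls})
            res.cells.append(cell)
    return res


def wetting_sweep(eps_fx_values, seeds=(1, 2, 3), scale: float = DESK_SCALE,
                  n_equil: int = 30_000,
                  n_production: int = 150_000) -> SweepResult:
    """X-on-F wetting vs the F-X attraction strength.

    Full four-component system with the +rDNA parameter set except the
    swept F-X value (matrices are built directly, since swept values below
    X-H deliberately leave the reference hierarchy).  Reports the coverage
    verdict and the F-X centre distance per value.
    """
    sp = scale_system(FULL_SPEC, scale)
    res = SweepResult(axes={"eps_FX": list(eps_fx_values), "seeds": list(seeds)})
    for eps in eps_fx_values:
        eps_map = dict(_PLUS_RDNA_EPS)
        eps_map[("F", "X")] = eps
        m = _build_matrix(eps_map, excluded=[("H", "F"), ("H", "rD"),
                                             ("rD", "rD"), ("rD", "X")])
        for seed in seeds:
            traj, _ = _run_cell(sp, m, seed, n_equil, n_production)
            rep = layering_verdict(traj.final_state())
            res.cells.append({
                "eps_FX": eps, "seed": seed, "coverage": rep.x_coverage_of_F,
                "wetting": rep.x_coverage_verdict, "d_FX": rep.d_FX,
                "verdict": rep.verdict})
    df = res.to_dataframe()
    res.thresholds["mean_d_FX_by_eps"] = {
        float(k): float(v) for k, v in df.groupby("eps_FX")["d_FX"].mean().items()}
    return res


def amphiphile_depletion_series(c_x_values, seeds=(1, 2, 3),
                                scale: float = DESK_SCALE,
                                n_equil: int = 30_000,
                                n_production: int = 150_000) -> SweepResult:
    """Layering vs amphiphile concentration, all other parameters fixed.

    Per concentration: the layering verdict, d_HF, and a nucleolar-edge
    occupancy analogue — the fraction of F-cluster surface beads with an H
    bead within the contact cutoff.  d_HF is expected non-decreasing as c_X
    decreases; violations are flagged.
    """
    from .model import SPECIES_INDEX
    matrix = plus_rdna_matrix()
    res = SweepResult(axes={"c_X": list(c_x_values), "seeds": list(seeds)})
    for c in c_x_values:
        sp = scale_system(FULL_SPEC, scale)
        n_x = count_from_concentration(c, sp.Rc)
        sp = sp.with_(n_X=n_x)
        for seed in seeds:
            traj, _ = _run_cell(sp, matrix, seed, n_equil, n_production)
            st = traj.final_state()
            rep = layering_verdict(st)
            f_pos = st.positions[st.species == SPECIES_INDEX["F"]]
            h_pos = st.positions[st.species == SPECIES_INDEX["H"]]
            f_cluster, _ = _largest_cluster_positions(f_pos)
            surface = f_cluster[_surface_mask(f_cluster)]
            if len(surface) and len(h_pos):
                d, _ = cKDTree(h_pos).query(surface, k=1)
                edge_occ = float(np.mean(d <= CLUSTER_CUTOFF))
            else:
                edge_occ = 0.0
            res.cells.append({"c_X": c, "n_X": n_x, "seed": seed,
                              "verdict": rep.verdict, "d_HF": rep.d_HF,
                              "h_edge_occupancy": edge_occ,
                              "coverage": rep.x_coverage_of_F})
    df = res.to_dataframe()
    means = df.groupby("c_X")["d_HF"].mean().sort_index()  # ascending c_X
    if np.any(np.diff(means.values) > 1e-9):
        # d_HF should not increase with more amphiphile
        res.flags.append("d_HF not non-decreasing as c_X decreases")
    res.thresholds["mean_d_HF_by_c_X"] = {
        float(k): float(v) for k, v in means.items()}
    return res
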