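"""End-to-end benchmark computations of the model's headline quantities.

Each function regenerates its system from scratch, runs the Langevin
protocol at the package's benchmark sizes and measures the result with the
observables module.  These are the computations behind
``scripts/acceptance.py`` and the acceptance-level tests; sizes and run
lengths (chosen so the whole battery fits a desk-scale compute budget, see
docs/methods.md) live here in one place.

All randomness is derived from a single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .engine import run_protocol
from .model import (GenomeModel, InteractionMatrix, SimulationParameters,
                    SPECIES_INDEX, confinement_radius_from_phi,
                    count_from_concentration)
from .observables import (find_clusters, is_condensed, layering_verdict,
                          radius_of_gyration)
from .scenarios import (FULL_SPEC, _build_matrix, _run_cell, minus_rdna_matrix,
                        plus_rdna_matrix, rdna_engulfment_sweep)
from .topology import SystemSpec, build_topology, initialize_positions, scale_system

# ---------------------------------------------------------------------------
# benchmark presets (problem sizes and run lengths; see docs/methods.md)
# ---------------------------------------------------------------------------
#: volume scale for single-component condensation columns (Rc = 22.5 sigma)
COND_SCALE = 1 / 8
#: condensation columns run quench-release: nucleate cold, then test the
#: cluster's stability at the working temperature
COND_SCALE_DILUTE = 2.0
COND_SCALE_DENSE = 1 / 8
COND_STEPS_DILUTE = 300_000
COND_STEPS_DENSE = 300_000
#: chain length, weak confinement and steps for the collapse sweep
COLLAPSE_N = 400
COLLAPSE_RC = 45.0
COLLAPSE_EQUIL = 250_000
COLLAPSE_PROD = 250_000
#: scale, annealing ladder and steps for four-component organization runs
ORG_SCALE = 1 / 24
ORG_ANNEAL_KBT = 1.3
ORG_ANNEAL_STEPS = 360_000
ORG_ANNEAL_STAGES = 6
ORG_EQUIL = 20_000
ORG_PROD = 80_000
WET_LO_SCALE = 1 / 32
ENGULF_SCALE = 1 / 32
ENGULF_PROD = 150_000


def _seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2 ** 31 - 1)


def confinement_radius() -> dict:
    """Confinement radius from the genome model (analytic)."""
    rc = confinement_radius_from_phi(GenomeModel())
    return {"value": rc, "rounded": float(round(rc)), "n": GenomeModel().NG}


def _condensed_at(c: float, eps: float, seed: int, n_steps: int,
                  scale: float = COND_SCALE_DENSE) -> tuple:
    """Direct-coexistence condensation call for one (c, eps) cell.

    The cell starts from a preformed droplet (60% of the beads packed at
    liquid density) surrounded by vapour and runs at the working
    temperature: a state inside the binodal keeps a majority cluster, one
    outside evaporates it.  This measures phase stability — what the
    phase diagram reports — rather than the spontaneous-nucleation rate,
    which at these bead counts is unobservably slow near the boundary.
    """
    from .engine import integrate
    from .topology import initialize_droplet_state
    Rc = FULL_SPEC.Rc * scale ** (1 / 3)
    n_f = count_from_concentration(c, Rc)
    m = InteractionMatrix().set_pair("F", "F", eps)
    topo = build_topology(0, 0.0, n_f, 0)
    params = SimulationParameters(Rc=Rc)
    state = initialize_droplet_state(topo, params, seed=_seed(seed, 3))
    integrate(state, topo, params, m, 1000, seed=_seed(seed, 4), fcap=20.0)
    traj = integrate(state, topo, params, m, n_steps, seed=_seed(seed, 6),
                     save_every=max(1, n_steps // 12))
    tail = [find_clusters(f) for f in traj.frames[-3:]]
    cond, frac, _ = is_condensed(tail, n_f)
    return cond, frac, n_f


def condensation_threshold(c: float, eps_grid, seed: int, n_steps: int):
    """Smallest attraction strength on the grid that condenses Fibrillarin.

    Scans upward and stops at the first condensing strength (the column is
    monotone in epsilon for a one-component system).  The dilute column
    runs at full nuclear volume (its bead count is small anyway), which
    reduces the curvature (Kelvin) penalty on its necessarily small
    droplet.
    """
    scale = COND_SCALE_DILUTE if c < 0.005 else COND_SCALE_DENSE
    fractions = {}
    threshold = float("nan")
    n_f = 0
    for eps in sorted(eps_grid):
        cond, frac, n_f = _condensed_at(c, eps, seed, n_steps, scale)
        fractions[eps] = frac
        if cond:
            threshold = eps
            break
    return {"value": threshold, "n": n_f, "fractions": fractions}


def collapse_onset(seed: int, eps_grid=(0.35, 0.40, 0.45)):
    """Smallest eps_HH on a 0.05 grid that collapses an isolated PCH chain.

    The chain sits in a weak confinement (Rc = 45 sigma for N = 400) so
    the athermal reference is a genuine self-avoiding coil; collapse is a
    production-averaged Rg below 0.6x that reference.
    """
    spec = SystemSpec(n_pch=COLLAPSE_N, rdna_fraction=0.0, n_F=0, n_X=0,
                      Rc=COLLAPSE_RC)

    def mean_rg(eps, k):
        m = (InteractionMatrix().set_pair("H", "H", eps) if eps > 0
             else InteractionMatrix().set_pair("H", "H", 0.0, "excluded_volume"))
        traj, _ = _run_cell(spec, m, _seed(seed, k), COLLAPSE_EQUIL,
                            COLLAPSE_PROD)
        half = traj.frames[len(traj.frames) // 2:]
        return float(np.mean([radius_of_gyration(f) for f in half]))

    rg0 = mean_rg(0.0, 0)
    rgs = {0.0: rg0}
    onset = float("nan")
    for i, eps in enumerate(eps_grid):
        eps = round(float(eps), 2)
        rg = mean_rg(eps, i + 1)
        rgs[eps] = rg
        if rg < 0.6 * rg0:
            onset = eps
            break  # grid is scanned upward; first crossing is the onset
    return {"value": onset, "n": COLLAPSE_N, "rg_reference": rg0, "rg": rgs}


def organization_run(kind: str, seed: int, eps_fx: float | None = None,
                     c_x: float | None = None, scale: float = ORG_SCALE,
                     n_production: int = ORG_PROD,
                     n_anneal: int = ORG_ANNEAL_STEPS):
    """One four-component scenario run, classified on the final frames.

    ``kind`` is 'plus-rdna' or 'minus-rdna'; ``eps_fx`` overrides the F-X
    attraction (wetting sweep points) and ``c_x`` the amphiphile
    concentration (depletion points).  Runs use the deposition-annealing
    ladder (hot hold with X in the vapour phase, slow cooling through the
    X condensation point) before production; the verdict is the majority
    over the final three saved frames (suppresses single-frame flicker).
    """
    sp = scale_system(FULL_SPEC, scale)
    if c_x is not None:
        sp = sp.with_(n_X=count_from_concentration(c_x, sp.Rc))
    if kind == "minus-rdna":
        matrix = minus_rdna_matrix()
    elif eps_fx is not None and eps_fx != 1.5:
        from .scenarios import _PLUS_RDNA_EPS
        eps_map = dict(_PLUS_RDNA_EPS)
        eps_map[("F", "X")] = eps_fx
        matrix = _build_matrix(eps_map, excluded=[("H", "F"), ("H", "rD"),
                                                  ("rD", "rD"), ("rD", "X")])
    else:
        matrix = plus_rdna_matrix()
    traj, _ = _run_cell(sp, matrix, seed, ORG_EQUIL, n_production,
                        anneal_kBT=ORG_ANNEAL_KBT, n_anneal=n_anneal,
                        anneal_stages=ORG_ANNEAL_STAGES)
    from .topology import SystemState
    reports = [layering_verdict(SystemState(
        positions=f.copy(), species=traj.species.copy(), Rc=traj.Rc))
        for f in traj.frames[-3:]]
    verdicts = [r.verdict for r in reports]
    majority = max(set(verdicts), key=verdicts.count)
    final = reports[-1]
    return {
        "verdict": majority, "verdicts": verdicts,
        "coverage": float(np.mean([r.x_coverage_of_F for r in reports
                                   if r.x_coverage_of_F is not None]))
        if any(r.x_coverage_of_F is not None for r in reports) else None,
        "coverage_verdict": final.x_coverage_verdict,
        "d_HF": float(np.mean([r.d_HF for r in reports if r.d_HF is not None]))
        if any(r.d_HF is not None for r in reports) else None,
        "d_FX": final.d_FX,
        "n": sp.n_pch + sp.n_F + sp.n_X,
        "report": final.to_dict(),
    }


def engulfment_point(eps_rdf: float, seed: int):
    """rDNA interior/wrapping classification for one rD-F attraction."""
    res = rdna_engulfment_sweep([eps_rdf], seeds=(seed,), scale=ENGULF_SCALE,
                                n_equil=30_000, n_production=ENGULF_PROD)
    cell = res.cells[-1]
    return {"classification": cell.get("classification"),
            "interior_fraction": cell.get("interior_fraction"),
            "contact_fraction": cell.get("contact_fraction"),
            "n": scale_system(FULL_SPEC.with_(n_X=0), ENGULF_SCALE).n_pch}


def diffusion_slope(seed: int, n_replicas: int = 64, n_steps: int = 120_000):
    """Fitted long-time MSD slope of a free bead (expect 6 kBT / (gamma m)).

    MSD is averaged over sliding time origins within each replica as well
    as over replicas, which brings the estimator noise well inside the
    10% acceptance band.
    """
    params = SimulationParameters(Rc=100.0)
    topo = build_topology(0, 0.0, n_F=1)
    from .engine import integrate
    from .topology import SystemState
    save_every = 400                       # frame spacing: 2 reduced time
    lag_max = 50                           # frames (100 reduced time)
    origin_stride = 25
    acc_msd = np.zeros(lag_max + 1)
    counts = np.zeros(lag_max + 1)
    for k in range(n_replicas):
        st = SystemState(positions=np.zeros((1, 3)), species=topo.species,
                         Rc=params.Rc)
        st.velocities = np.zeros((1, 3))
        traj = integrate(st, topo, params, InteractionMatrix(), n_steps,
                         seed=_seed(seed, 100 + k), save_every=save_every)
        x = traj.frames[:, 0, :]
        for t0 in range(0, len(x) - lag_max, origin_stride):
            d = x[t0:t0 + lag_max + 1] - x[t0]
            acc_msd += np.sum(d * d, axis=1)
            counts += 1
    lags = np.arange(lag_max + 1) * save_every * params.dt
    msd = acc_msd / counts
    sel = lags >= 20
    slope = np.polyfit(lags[sel], msd[sel], 1)[0]
    return {"value": float(slope), "n": n_replicas,
            "expected": 6.0 * params.kBT / (params.gamma * params.mass)}


def saw_exponent(seed: int, lengths=(50, 100, 200, 400)):
    """Flory exponent from athermal-chain Rg scaling, Rg ~ N^nu.

    Chains relax in a wide confinement; equilibration scales steeply with
    chain length, so run lengths grow with N (the initial growth-walk
    configurations are more compact than true self-avoiding coils).
    """
    params = SimulationParameters(Rc=45.0)
    m = InteractionMatrix().set_pair("H", "H", 0.0, "excluded_volume")
    rgs = []
    for i, n in enumerate(lengths):
        topo = build_topology(n, 0.0)
        n_equil = max(60_000, int(400_000 * (n / 400) ** 1.5))
        traj, _ = run_protocol(topo, params, m, seed=_seed(seed, 200 + i),
                               n_pushoff=0, n_equil=n_equil,
                               n_production=max(100_000, n_equil),
                               save_every=20_000)
        half = traj.frames[len(traj.frames) // 2:]
        rgs.append(np.mean([radius_of_gyration(f) for f in half]))
    nu = float(np.polyfit(np.log(lengths), np.log(rgs), 1)[0])
    return {"value": nu, "n": max(lengths), "rg": dict(zip(lengths, map(float, rgs)))}


def imaging_recovery(seed: int):
    """Metric recovery on generated volumes with known ground truth."""
    from . import imaging as im
    from .synth import NucleusGeometry, generate_nucleus_volume

    out = {}
    _, masks = generate_nucleus_volume("surrounded", noise=0.0, seed=seed)
    out["shell_occupancy_truth"] = im.shell_occupancy(
        masks["fibrillarin"], masks["pch"], 1)
    image, _ = generate_nucleus_volume(
        "extended", geometry=NucleusGeometry(aspect_ratio=2.0),
        noise=0.05, seed=_seed(seed, 7))
    seg = im.segment_channel(image, "pch", gaussian_sigma=1.0)
    out["aspect_ratio_recovered"] = im.aspect_ratio_2d(seg.mask().max(axis=0))
    image, masks = generate_nucleus_volume("void", noise=0.0, seed=seed)
    segp = im.segment_channel(image, "protein")
    out["void_core_volume_um3"] = float(im.object_volume(segp).sum())
    out["void_core_volume_truth_um3"] = float(masks["protein"].sum() * 0.1 ** 3)
    return out
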