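"""Text I/O: extended-XYZ trajectories, topology sidecars, reports.

Trajectory frames go to extended-XYZ (species as the atom label, with
``Time`` and ``Rc`` in the comment line); topology/bond/provenance metadata
go to JSON sidecars; per-run observable logs to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SPECIES, SPECIES_INDEX
from .topology import SystemState, Topology

__all__ = ["write_extxyz", "read_extxyz", "write_trajectory",
           "read_trajectory_final_state", "save_topology", "load_topology",
           "write_json", "write_run_log"]


def write_extxyz(path, frames, species_codes, Rc, times=None, mode="w"):
    """Write frames (F, N, 3) to extended-XYZ; species as atom labels."""
    names = np.asarray(SPECIES, dtype=object)[np.asarray(species_codes)]
    times = times if times is not None else np.zeros(len(frames))
    with open(path, mode) as fh:
        for frame, t in zip(frames, times):
            fh.write(f"{len(frame)}\n")
            fh.write(f'Properties=species:S:1:pos:R:3 Time={t:.6f} Rc={Rc:.6f}\n')
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def read_extxyz(path):
    """Read an extended-XYZ file -> list of (species_names, positions, meta)."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline()
            meta = {}
            for tok in comment.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            names, pos = [], np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                pos[i] = [float(p) for p in parts[1:4]]
            frames.append((names, pos, meta))
    return frames


def write_trajectory(traj, path):
    """Trajectory -> extxyz + a .meta.json sidecar with full provenance."""
    path = Path(path)
    write_extxyz(path, traj.frames, traj.species, traj.Rc, traj.times)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    write_json(sidecar, {
        "Rc": traj.Rc, "save_every": traj.save_every,
        "species_counts": {s: int(np.sum(traj.species == SPECIES_INDEX[s]))
                           for s in SPECIES},
        "provenance": traj.provenance,
    })
    return sidecar


def read_trajectory_final_state(path) -> SystemState:
    frames = read_extxyz(path)
    names, pos, meta = frames[-1]
    codes = np.array([SPECIES_INDEX[n] for n in names], dtype=np.int8)
    return SystemState(positions=pos, species=codes,
                       Rc=float(meta.get("Rc", np.inf)),
                       time=float(meta.get("Time", 0.0)))


def save_topology(topology: Topology, path):
    write_json(path, {
        "species": [SPECIES[c] for c in topology.species],
        "bonds": topology.bonds.tolist(),
        "angles": topology.angles.tolist(),
        "n_polymer": topology.n_polymer,
        "h_blocks": list(map(list, topology.h_blocks)),
        "rd_block": list(topology.rd_block),
    })


def load_topology(path) -> Topology:
    d = json.loads(Path(path).read_text())
    return Topology(
        species=np.array([SPECIES_INDEX[s] for s in d["species"]], np.int8),
        bonds=np.asarray(d["bonds"], np.int32).reshape(-1, 2),
        angles=np.asarray(d["angles"], np.int32).reshape(-1, 3),
        n_polymer=d["n_polymer"],
        h_blocks=tuple(tuple(b) for b in d["h_blocks"]),
        rd_block=tuple(d["rd_block"]),
    )


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(path, obj):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return Path(path)


def write_run_log(traj, path):
    """Per-frame step/time/potential-energy/kinetic-temperature CSV."""
    n = len(traj.kinetic_temps)
    df = pd.DataFrame({
        "time": traj.times[-n:] if n else [],
        "potential_energy": traj.potential_energies,
        "kinetic_temperature": traj.kinetic_temps,
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return Path(path)
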