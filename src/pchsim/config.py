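"""Run configuration: a flat INI dialect shared by the simulator and the
imaging half, with full default materialization, invariant validation and a
content hash sufficient to reproduce any run bit-identically.

Sections: ``[run]`` (command, seed, out, log_level), ``[params]``
(integrator/physical constants), ``[system]`` (counts, scale, fractions),
``[protocol]`` (stage lengths), ``[pairs]`` (interaction overrides such as
``XX = 1.75``).  Unknown keys are rejected by name.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field, fields as dc_fields

from .model import SimulationParameters
from .scenarios import DESK_SCALE, FULL_SPEC, minus_rdna_matrix, plus_rdna_matrix
from .topology import SystemSpec, scale_system

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_PARAM_KEYS = {f.name for f in dc_fields(SimulationParameters)}
_SYSTEM_KEYS = {"scale", "n_pch", "rdna_fraction", "n_f", "n_x", "rc"}
_RUN_KEYS = {"command", "seed", "out", "log_level"}
_PROTOCOL_KEYS = {"n_pushoff", "n_equil", "n_production", "save_every"}
_PAIR_KEYS = {"ff", "rdf", "xx", "fx", "xh", "hh"}
_PAIR_NAME = {"ff": "FF", "rdf": "rDF", "xx": "XX", "fx": "FX",
              "xh": "XH", "hh": "HH"}

_DEFAULTS = {
    "run": {"command": "sim.scenario.plus-rdna", "seed": "1",
            "out": "runs/out", "log_level": "info"},
    "system": {"scale": str(DESK_SCALE)},
    "protocol": {"n_pushoff": "2000", "n_equil": "50000",
                 "n_production": "200000", "save_every": "0"},
}


@dataclass
class RunConfig:
    """Fully resolved run configuration (all defaults materialized)."""

    command: str
    seed: int
    out: str
    log_level: str
    params: SimulationParameters
    system: SystemSpec
    scale: float
    protocol: dict
    pair_overrides: dict = field(default_factory=dict)
    config_hash: str = ""
    sections: dict = field(default_factory=dict)

    def to_ini(self) -> str:
        """Canonical structured-text form; re-loading it reproduces the
        same hash (and therefore the same run)."""
        lines = []
        for sec in sorted(self.sections):
            lines.append(f"[{sec}]")
            for k, v in sorted(self.sections[sec].items()):
                lines.append(f"{k} = {v}")
            lines.append("")
        return "\n".join(lines)

    def matrix(self):
        if self.command.endswith("minus-rdna"):
            return minus_rdna_matrix(
                x_h=self.pair_overrides.get("XH", 1.5))
        return plus_rdna_matrix(**self.pair_overrides)

    def scaled_spec(self) -> SystemSpec:
        return scale_system(self.system, self.scale)


def _canonical(sections: dict) -> str:
    lines = [f"{sec}.{k}={v}" for sec in sorted(sections)
             for k, v in sorted(sections[sec].items())]
    return "\n".join(lines)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load + validate a config file, merge defaults, compute the hash.

    ``overrides`` maps ``"section.key"`` to values (CLI flags take
    precedence over file keys).  An empty file (or no file) yields the full
    default desk-scale +rDNA configuration.  Unknown keys, type errors and
    violated invariants raise :class:`ConfigError` naming key and rule.
    """
    cp = configparser.ConfigParser()
    if path is not None:
        with open(path) as fh:
            cp.read_file(fh)
    sections = {sec: dict(cp.items(sec)) for sec in cp.sections()}
    for dotted, value in (overrides or {}).items():
        sec, key = dotted.split(".", 1)
        sections.setdefault(sec, {})[key.lower()] = str(value)

    known = {"run": _RUN_KEYS, "params": _PARAM_KEYS, "system": _SYSTEM_KEYS,
             "protocol": _PROTOCOL_KEYS, "pairs": _PAIR_KEYS}
    for sec, kv in sections.items():
        if sec not in known:
            raise ConfigError(f"unknown section [{sec}]")
        for key in kv:
            if key.lower() not in known[sec]:
                raise ConfigError(f"unknown key {key!r} in section [{sec}]")

    merged = {sec: dict(kv) for sec, kv in _DEFAULTS.items()}
    for sec, kv in sections.items():
        merged.setdefault(sec, {}).update({k.lower(): v for k, v in kv.items()})

    def get(sec, key, cast, default=None):
        raw = merged.get(sec, {}).get(key, default)
        if raw is None:
            return None
        try:
            return cast(raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{sec}.{key}: cannot parse {raw!r}: {exc}") from exc

    try:
        pkw = {k: (int if k in ("n_steps", "seed") else float)(v)
               for k, v in merged.get("params", {}).items()}
        params = SimulationParameters(**pkw)
    except ValueError as exc:
        raise ConfigError(f"params: {exc}") from exc

    system = FULL_SPEC
    sys_kv = merged.get("system", {})
    sys_map = {"n_pch": ("n_pch", int), "rdna_fraction": ("rdna_fraction", float),
               "n_f": ("n_F", int), "n_x": ("n_X", int), "rc": ("Rc", float)}
    kw = {}
    for key, (attr, cast) in sys_map.items():
        if key in sys_kv:
            kw[attr] = get("system", key, cast)
    system = system.with_(**kw)
    scale = get("system", "scale", float, str(DESK_SCALE))

    pair_overrides = {}
    for key, val in merged.get("pairs", {}).items():
        pair_overrides[_PAIR_NAME[key]] = get("pairs", key, float)

    protocol = {k: get("protocol", k, int) for k in _PROTOCOL_KEYS}
    cfg = RunConfig(
        command=get("run", "command", str),
        seed=get("run", "seed", int),
        out=get("run", "out", str),
        log_level=get("run", "log_level", str),
        params=params, system=system, scale=scale, protocol=protocol,
        pair_overrides=pair_overrides,
        config_hash=hashlib.sha256(_canonical(merged).encode()).hexdigest(),
        sections=merged,
    )
    # delegate matrix invariants (hierarchy) to the scenario validators
    if cfg.command.endswith("plus-rdna") or cfg.command == "sim.scenario":
        try:
            cfg.matrix()
        except ValueError as exc:
            raise ConfigError(f"pairs: {exc}") from exc
    return cfg
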