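"""Run configuration: TOML parsing, validation, and deterministic seeding.

A run config selects one model (``abm``, ``pde-full``, ``pde-slow`` or
``pde-treatment``) and carries the parameter blocks for it.  Unknown keys
are rejected so typos cannot silently fall back to defaults, and every
run's fully resolved config travels into the output metadata.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RunConfig", "load_config", "loads_config", "dumps_config",
           "spawn_seeds", "ConfigError"]


class ConfigError(ValueError):
    pass


MODELS = ("abm", "pde-full", "pde-slow", "pde-treatment")

_SCHEMA = {
    "run": {"model", "seed"},
    "abm": {"nx", "ny", "mu", "p_div", "rho_max", "p_s", "alpha",
            "neighborhood", "n_mcs", "snapshot_every"},
    "pde": {"alpha", "d", "epsilon", "delta", "crowding", "domain_length",
            "dx", "t_end", "n_output", "ic_edge"},
    "treatment": {"protocol", "start", "delta", "baseline_alpha", "on",
                  "off", "horizon", "total_dose_cap", "R0", "lam", "omega",
                  "alpha_r", "beta_r", "dose_per_fraction",
                  "fraction_duration", "mode"},
    "measurement": {"threshold", "window_start"},
    "output": {"hdf5", "csv", "kymograph"},
}

_DEFAULTS = {
    "run": {"model": "pde-slow", "seed": 0},
    "pde": {"alpha": 0.5, "d": 1.0, "epsilon": 0.01, "delta": 0.0,
            "crowding": "linear", "domain_length": 200.0, "dx": 0.1,
            "t_end": 80.0, "n_output": 81, "ic_edge": 20.0},
    "abm": {"nx": 500, "ny": 50, "mu": 1.0, "p_div": 1.0 / 24, "rho_max": 15,
            "p_s": 0.01, "alpha": 0.0, "neighborhood": "moore",
            "n_mcs": 7000, "snapshot_every": 50},
    "measurement": {"threshold": 0.5, "window_start": 0.5},
}


@dataclass
class RunConfig:
    model: str
    seed: int = 0
    sections: dict = field(default_factory=dict)

    def section(self, name):
        return dict(self.sections.get(name, {}))

    def resolved(self) -> dict:
        """Plain dict form (goes into output metadata)."""
        out = {"run": {"model": self.model, "seed": self.seed}}
        out.update({k: dict(v) for k, v in self.sections.items()})
        return out


def _validate_tree(data: dict):
    for sect, keys in data.items():
        if sect not in _SCHEMA:
            raise ConfigError(f"unknown config section [{sect}]")
        if not isinstance(keys, dict):
            raise ConfigError(f"[{sect}] must be a table")
        for k in keys:
            if k not in _SCHEMA[sect]:
                raise ConfigError(f"unknown key {k!r} in section [{sect}]")


def _build(data: dict) -> RunConfig:
    _validate_tree(data)
    run = {**_DEFAULTS["run"], **data.get("run", {})}
    model = run["model"]
    if model not in MODELS:
        raise ConfigError(f"run.model must be one of {MODELS}, got {model!r}")
    if model == "abm" and "pde" in data:
        raise ConfigError("sections [abm] and [pde] are mutually exclusive "
                          "with run.model='abm'")
    if model.startswith("pde") and "abm" in data:
        raise ConfigError("section [abm] is not allowed for a PDE model")
    if model == "pde-treatment" and "treatment" not in data:
        raise ConfigError("model 'pde-treatment' requires a [treatment] section")
    sections = {}
    for name in ("abm", "pde", "measurement"):
        if name in data or name in _DEFAULTS and (
            name == "measurement" or name.split("-")[0] in model
        ):
            base = dict(_DEFAULTS.get(name, {}))
            base.update(data.get(name, {}))
            sections[name] = base
    for name in ("treatment", "output"):
        if name in data:
            sections[name] = dict(data[name])
    # basic value validation with key-naming errors
    pde = sections.get("pde", {})
    if "alpha" in pde and pde["alpha"] <= 0:
        raise ConfigError("pde.alpha must be positive")
    if "d" in pde and pde["d"] <= 0:
        raise ConfigError("pde.d must be positive")
    abm = sections.get("abm", {})
    if "alpha" in abm and abm["alpha"] < 0:
        raise ConfigError("abm.alpha must be non-negative")
    return RunConfig(model=model, seed=int(run["seed"]), sections=sections)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        return _build(tomllib.load(fh))


def loads_config(text: str) -> RunConfig:
    return _build(tomllib.loads(text))


def _fmt(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {v!r} to TOML")


def dumps_config(cfg: RunConfig) -> str:
    """Serialize back to TOML; ``loads_config(dumps_config(c))`` is identity."""
    lines = []
    for sect, table in cfg.resolved().items():
        lines.append(f"[{sect}]")
        for k, v in table.items():
            lines.append(f"{k} = {_fmt(v)}")
        lines.append("")
    return "\n".join(lines)


def spawn_seeds(seed, n):
    """Expand one master seed into n independent 31-bit child seeds.

    Child streams never share draws (SeedSequence spawning), so the ABM
    and any stochastic initial condition stay decoupled.
    """
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(n)]
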