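"""Flat YAML configs for scenarios, runs and sweeps.

Config files are flat key/value mappings whose keys mirror the dataclass
fields of :class:`~strutdiff.frap_synth.BleachScenario`,
:class:`~strutdiff.geometry.ScaffoldSpec` and
:class:`~strutdiff.solver.KineticParams`, plus a handful of run options
(``dt_growth``, ``t_end``, ``steady_eps``, ``threshold_frac``,
``use_symmetry``).  Unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .frap_synth import BleachScenario
from .geometry import ScaffoldSpec
from .solver import KineticParams

RUN_OPTION_DEFAULTS: dict[str, Any] = {
    "dt_growth": 2.0,
    "t_end": 2400.0,
    "steady_eps": 1e-3,
    "threshold_frac": 0.99,
    "use_symmetry": True,
}


def _fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _pick(data: dict, cls):
    names = _fields(cls)
    return cls(**{k: v for k, v in data.items() if k in names})


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return data


def load_scenario(path) -> BleachScenario:
    data = load_yaml(path)
    unknown = set(data) - _fields(BleachScenario)
    if unknown:
        raise ValueError(f"{path}: unknown scenario keys {sorted(unknown)}")
    return _pick(data, BleachScenario)


def load_run_config(path) -> tuple[ScaffoldSpec, KineticParams, dict]:
    """Read a scaffold run config -> (spec, params, run options).

    ``ds_over_dw`` may be given instead of ``d_s``; it is resolved
    against ``d_w``.
    """
    data = dict(load_yaml(path))
    if "ds_over_dw" in data:
        ratio = data.pop("ds_over_dw")
        d_w = data.get("d_w", KineticParams().d_w)
        data["d_s"] = ratio * d_w
    allowed = _fields(ScaffoldSpec) | _fields(KineticParams) | set(RUN_OPTION_DEFAULTS)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown run keys {sorted(unknown)}")
    spec = _pick(data, ScaffoldSpec)
    params = _pick(data, KineticParams)
    options = {k: data.get(k, v) for k, v in RUN_OPTION_DEFAULTS.items()}
    return spec, params, options


def load_sweep_config(path) -> dict:
    """Read a sweep config: list-valued ``alphas``, ``arrangements``,
    ``ds_over_dw`` plus any run-config scalars applied to every run."""
    data = dict(load_yaml(path))
    lists = {
        "alphas": data.pop("alphas", [0.5]),
        "arrangements": data.pop("arrangements", ["lattice"]),
        "ds_over_dw": data.pop("ds_over_dw", [0.0, 1.0]),
    }
    allowed = _fields(ScaffoldSpec) | _fields(KineticParams) | set(RUN_OPTION_DEFAULTS)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown sweep keys {sorted(unknown)}")
    lists["spec"] = _pick({**data, "alpha": lists["alphas"][0]}, ScaffoldSpec)
    lists["params"] = _pick(data, KineticParams)
    lists["options"] = {k: data.get(k, v) for k, v in RUN_OPTION_DEFAULTS.items()}
    return lists
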