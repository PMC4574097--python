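"""Packaged channel and block parameter sets (YAML, units in comments)."""

from __future__ import annotations

import importlib.resources as _res
from pathlib import Path
from typing import Union

import yaml

from ..model import BlockParams, ChannelParams, TauSpec, WeightSpec, apply_kcne2

__all__ = ["available_params", "load_params", "load_block", "params_from_dict"]

_NAMES = ("equine", "human", "equine_kcne2")


def available_params() -> tuple:
    return _NAMES


def _read_yaml(name: str) -> dict:
    text = _res.files(__package__).joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def params_from_dict(d: dict) -> ChannelParams:
    """Build :class:`ChannelParams` from the structured-config mapping."""
    known = {"label", "g_max", "e_rev", "v_half_act", "k_act",
             "v_half_inact", "k_inact", "tau_act", "tau_act_slow",
             "w_fast", "tau_inact"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ChannelParams(
        g_max=float(d["g_max"]),
        e_rev=float(d["e_rev"]),
        v_half_act=float(d["v_half_act"]),
        k_act=float(d["k_act"]),
        v_half_inact=float(d["v_half_inact"]),
        k_inact=float(d["k_inact"]),
        tau_act_spec=TauSpec(**d["tau_act"]),
        tau_inact_spec=TauSpec(**d["tau_inact"]),
        tau_act_slow_spec=TauSpec(**d["tau_act_slow"]) if "tau_act_slow" in d else None,
        w_fast_spec=WeightSpec(**d["w_fast"]) if "w_fast" in d else None,
        label=str(d.get("label", "")),
    )


def load_params(name_or_path: Union[str, Path]) -> ChannelParams:
    """Load a packaged parameter set by name, or any YAML file by path."""
    name = str(name_or_path)
    if name in _NAMES:
        d = _read_yaml(name)
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValueError(
                f"unknown parameter set {name!r}; packaged sets: {_NAMES}")
        d = yaml.safe_load(path.read_text())
    if "base" in d:  # derived set, e.g. KCNE2 co-expression
        base = load_params(d["base"])
        return apply_kcne2(base, float(d["kcne2_reduction"]))
    return params_from_dict(d)


def load_block(name: str) -> BlockParams:
    """Load a packaged Hill block parameter set (terfenadine_steady / _tail)."""
    table = _read_yaml("blocks")
    if name not in table:
        raise ValueError(f"unknown block set {name!r}; available: {sorted(table)}")
    return BlockParams(**table[name])
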