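"""Load and validate the biophysical parameter file.

All model constants — channel densities, synaptic kinetics, input
calibration — live in a versioned JSON file (``params/cells.json``) so that
alternative parameterizations can be swapped without code changes.
"""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

__all__ = ["load_params", "default_params", "ParamError"]


class ParamError(ValueError):
    """Raised when the parameter file violates the schema."""


_CELL_CLASSES = ("PN", "eLN", "LN")
_SYNAPSE_CLASSES = ("nACh", "GABA_A", "GABA_B")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParamError(msg)


def _validate_cell(name: str, cell: dict[str, Any]) -> None:
    _require(cell["capacitance_uF"] > 0, f"{name}: capacitance must be > 0")
    _require(cell["leak"]["g_uS"] >= 0, f"{name}: leak conductance must be >= 0")
    for ch, rec in cell["channels"].items():
        _require(rec["g_uS"] >= 0, f"{name}.{ch}: conductance must be >= 0")
    pool = cell.get("ca_pool")
    if pool is not None:
        _require(pool["tau_ms"] > 0, f"{name}: calcium decay tau must be > 0")
        _require(pool["rest"] >= 0, f"{name}: resting calcium must be >= 0")
    spike = cell["spike"]
    _require(spike["mode"] in ("threshold_crossing", "local_max"),
             f"{name}: unknown spike mode {spike['mode']!r}")


def _validate(params: dict[str, Any]) -> None:
    for key in ("cells", "synapses", "input"):
        _require(key in params, f"missing top-level section {key!r}")
    for name in _CELL_CLASSES:
        _require(name in params["cells"], f"missing cell class {name!r}")
        _validate_cell(name, params["cells"][name])
    # eLNs are PNs by construction
    _require(params["cells"]["eLN"] == params["cells"]["PN"],
             "eLN parameters must equal PN parameters")
    for name in _SYNAPSE_CLASSES:
        _require(name in params["synapses"], f"missing synapse class {name!r}")
        syn = params["synapses"][name]
        for k, v in syn.items():
            if k.endswith("_per_ms"):
                _require(v > 0, f"{name}.{k}: rate constants must be > 0")
    _require(params["synapses"]["GABA_A"]["E_mV"] <= -70,
             "GABA_A reversal must be <= -70 mV (inhibitory)")
    _require(params["synapses"]["GABA_B"]["E_mV"] <= -70,
             "GABA_B reversal must be <= -70 mV (inhibitory)")
    _require(params["synapses"]["nACh"]["E_mV"] >= 0,
             "nACh reversal must be >= 0 mV (excitatory)")
    inp = params["input"]
    _require(inp["sigma_x"] > 0, "input sigma must be > 0")
    _require(0 <= inp["truncation"] < 1, "truncation must lie in [0, 1)")
    _require(inp["noise_fraction"] >= 0, "noise fraction must be >= 0")


def load_params(path: str | Path) -> dict[str, Any]:
    """Load a parameter file and validate it against the schema."""
    with open(path) as fh:
        params = json.load(fh)
    _validate(params)
    return params


def default_params() -> dict[str, Any]:
    """The package's default locust antennal-lobe parameterization."""
    ref = resources.files("alnet") / "params" / "cells.json"
    params = json.loads(ref.read_text())
    _validate(params)
    return params
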