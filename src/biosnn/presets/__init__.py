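"""Shipped neuron presets (FS, RS, IB, LTS) as validated JSON data files.

Each preset file parameterizes one cortical firing class of the Pospischil
single-compartment model.  The engine treats presets purely as data: any gate
can be re-pointed at a different kinetics family or given new parameters, and
new presets can be added as files without touching the solver.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2 (stated in every file).
"""

from __future__ import annotations

import json
from importlib import resources

from ..hh_core import (
    ConfigError,
    CurrentSpec,
    NeuronModelParams,
    OUNoiseParams,
    make_gate,
)

__all__ = ["list_presets", "load_preset", "params_from_dict", "params_to_dict"]

_REQUIRED = ("preset_id", "C_m", "g_leak", "E_leak", "currents")


def list_presets() -> list[str]:
    files = resources.files(__name__) / "data"
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".json"))


def load_preset(name: str, noise: OUNoiseParams | None = None) -> NeuronModelParams:
    """Load a shipped preset by id, optionally overriding its noise block."""
    path = resources.files(__name__) / "data" / f"{name}.json"
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"unknown preset {name!r}; shipped: {list_presets()}") from None
    params = params_from_dict(raw)
    if noise is not None:
        params = NeuronModelParams(
            preset_id=params.preset_id,
            C_m=params.C_m,
            g_leak=params.g_leak,
            E_leak=params.E_leak,
            currents=params.currents,
            noise=noise,
            spike_threshold=params.spike_threshold,
        )
    return params


def params_from_dict(raw: dict) -> NeuronModelParams:
    """Build and validate a :class:`NeuronModelParams` from plain JSON data."""
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"preset is missing required fields {missing}")
    currents = []
    for cur in raw["currents"]:
        gates = tuple(
            make_gate(
                name=g.get("name", f"{cur['name']}_{g['family']}"),
                family=g["family"],
                exponent=int(g["exponent"]),
                params=g.get("params", {}),
            )
            for g in cur["gates"]
        )
        currents.append(
            CurrentSpec(
                name=cur["name"],
                g_max=float(cur["g_max"]),
                E_rev=float(cur["E_rev"]),
                gates=gates,
            )
        )
    noise_raw = raw.get("noise", {})
    noise = OUNoiseParams(
        mu=float(noise_raw.get("mu", 0.0)),
        theta=float(noise_raw.get("theta", 0.1)),
        sigma=float(noise_raw.get("sigma", 0.0)),
    )
    return NeuronModelParams(
        preset_id=raw["preset_id"],
        C_m=float(raw["C_m"]),
        g_leak=float(raw["g_leak"]),
        E_leak=float(raw["E_leak"]),
        currents=tuple(currents),
        noise=noise,
        spike_threshold=float(raw.get("spike_threshold", 0.0)),
    )


def params_to_dict(params: NeuronModelParams) -> dict:
    """Serialize a preset back to plain JSON data (inverse of params_from_dict
    for presets built from named kinetics families)."""
    currents = []
    for cur in params.currents:
        gates = []
        for g in cur.gates:
            if g.family == "custom":
                raise ConfigError(
                    f"gate {g.name!r} uses custom callables and cannot be serialized"
                )
            gates.append(
                {"name": g.name, "family": g.family, "exponent": g.exponent, "params": g.params}
            )
        currents.append(
            {"name": cur.name, "g_max": cur.g_max, "E_rev": cur.E_rev, "gates": gates}
        )
    return {
        "preset_id": params.preset_id,
        "units": {
            "voltage": "mV",
            "time": "ms",
            "current": "uA/cm^2",
            "conductance": "mS/cm^2",
            "capacitance": "uF/cm^2",
        },
        "C_m": params.C_m,
        "g_leak": params.g_leak,
        "E_leak": params.E_leak,
        "spike_threshold": params.spike_threshold,
        "noise": {
            "mu": params.noise.mu,
            "theta": params.noise.theta,
            "sigma": params.noise.sigma,
        },
        "currents": currents,
    }
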