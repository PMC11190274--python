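"""Kinetic receptor models (AMPA, NMDA, GABA_A, GABA_B) and synaptic currents.

Receptors follow the Destexhe-style first-order ligand-binding scheme: a
presynaptic spike releases a square transmitter pulse [T] of amplitude
``T_max`` (mM) for ``T_dur`` (ms); the bound fraction r obeys

    dr/dt = alpha * [T] * (1 - r) - beta * r

The postsynaptic conductance is g_max * activation, with

    AMPA, GABA_A : activation = r
    NMDA         : activation = B(V) * r      (voltage-dependent Mg2+ block)
    GABA_B       : activation = s^n / (s^n + Kd), ds/dt = K3*r - K4*s
                   (second-messenger / K+ channel cascade)

Receptor currents are computed in the ohmic convention
I = w * g_max * activation * (V_post - E_rev); the membrane equation negates
them.  Synaptic weights are stored as 14-bit fixed-point codes and scaled by
a global software weight factor mimicking a larger network.

Default kinetic constants are the published Destexhe-model fits, shipped in
:data:`DEFAULT_RECEPTORS`; the transmitter pulse defaults to 1 mM for 1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hh_core import ConfigError
from .numerics import DEFAULT_FORMATS, dequantize, quantize

__all__ = [
    "RECEPTOR_KINDS",
    "ReceptorParams",
    "ReceptorState",
    "Synapse",
    "SynapseSet",
    "DEFAULT_RECEPTORS",
    "receptor_step",
    "nmda_mg_block",
    "gabab_activation",
    "synaptic_current",
    "weight_to_code",
    "code_to_weight",
]

RECEPTOR_KINDS = ("AMPA", "NMDA", "GABA_A", "GABA_B")

WEIGHT_FORMAT = DEFAULT_FORMATS["weight"]


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetic constants of one receptor kind.

    ``alpha`` (1/(mM ms)) and ``beta`` (1/ms) are the transmitter binding and
    unbinding rates; ``Mg`` applies to NMDA only; ``K3``/``K4``/``Kd``/``n``
    parameterize the GABA_B second-messenger cascade.
    """

    kind: str
    alpha: float
    beta: float
    g_max: float
    E_rev: float
    T_max: float = 1.0
    T_dur: float = 1.0
    Mg: float = 1.0
    K3: float = 0.0
    K4: float = 0.0
    Kd: float = 100.0
    n: int = 4

    def __post_init__(self) -> None:
        if self.kind not in RECEPTOR_KINDS:
            raise ConfigError(f"unknown receptor kind {self.kind!r}")
        if min(self.alpha, self.beta, self.g_max, self.K3, self.K4) < 0:
            raise ConfigError(f"{self.kind}: rates and g_max must be >= 0")
        if self.T_dur <= 0:
            raise ConfigError(f"{self.kind}: T_dur must be > 0")
        if self.n < 1:
            raise ConfigError(f"{self.kind}: Hill coefficient n must be >= 1")


# Destexhe-model kinetic fits; g_max values are per-synapse defaults in
# mS/cm^2, deliberately small because drive sums over many synapses.
DEFAULT_RECEPTORS: dict[str, ReceptorParams] = {
    "AMPA": ReceptorParams(kind="AMPA", alpha=1.1, beta=0.19, g_max=0.1, E_rev=0.0),
    "NMDA": ReceptorParams(kind="NMDA", alpha=0.072, beta=0.0066, g_max=0.05, E_rev=0.0, Mg=1.0),
    "GABA_A": ReceptorParams(kind="GABA_A", alpha=5.0, beta=0.18, g_max=0.1, E_rev=-80.0),
    "GABA_B": ReceptorParams(
        kind="GABA_B",
        alpha=0.09,
        beta=0.0012,
        g_max=0.06,
        E_rev=-95.0,
        K3=0.18,
        K4=0.034,
        Kd=100.0,
        n=4,
    ),
}


@dataclass
class ReceptorState:
    """Bound fraction r in [0,1], second messenger s >= 0 (GABA_B), and the
    remaining transmitter-pulse time in ms."""

    r: float = 0.0
    s: float = 0.0
    pulse_remaining: float = 0.0


def receptor_step(
    state: ReceptorState, p: ReceptorParams, presyn_spike: bool, dt: float
) -> ReceptorState:
    """Advance one receptor by dt; a presynaptic spike (re)starts the pulse."""
    pulse = p.T_dur if presyn_spike else state.pulse_remaining
    T = p.T_max if pulse > 0 else 0.0
    r = state.r + dt * (p.alpha * T * (1.0 - state.r) - p.beta * state.r)
    r = min(1.0, max(0.0, r))
    s = state.s
    if p.kind == "GABA_B":
        s = max(0.0, s + dt * (p.K3 * state.r - p.K4 * s))
    return ReceptorState(r=r, s=s, pulse_remaining=max(0.0, pulse - dt))


def nmda_mg_block(V, Mg: float = 1.0):
    """Voltage-dependent magnesium block factor B(V) in (0, 1]."""
    if Mg < 0:
        raise ConfigError("Mg concentration must be >= 0")
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(V, dtype=np.float64)) * Mg / 3.57)


def gabab_activation(s, Kd: float = 100.0, n: int = 4):
    """GABA_B channel opening s^n / (s^n + Kd), in [0, 1) and monotone in s."""
    sn = np.asarray(s, dtype=np.float64) ** n
    return sn / (sn + Kd)


def _activation(state: ReceptorState, p: ReceptorParams, post_V: float) -> float:
    if p.kind == "NMDA":
        return float(nmda_mg_block(post_V, p.Mg)) * state.r
    if p.kind == "GABA_B":
        return float(gabab_activation(state.s, p.Kd, p.n))
    return state.r


def synaptic_current(
    post_V: float,
    incoming: list[tuple[ReceptorState, ReceptorParams, int]],
    weight_factor: float = 1.0,
) -> float:
    """Total receptor current onto one neuron, ohmic convention (uA/cm^2).

    ``incoming`` holds (state, params, weight_code) per afferent synapse with
    the weight as a 14-bit fixed-point code.  Positive values are outward
    (hyperpolarizing); the membrane equation negates this sum.
    """
    I = 0.0
    for state, p, code in incoming:
        w = code_to_weight(code)
        I += w * weight_factor * p.g_max * _activation(state, p, post_V) * (post_V - p.E_rev)
    return I


def weight_to_code(w: float) -> int:
    """Quantize a real weight to the 14-bit fixed-point code."""
    return int(quantize(float(w), WEIGHT_FORMAT))


def code_to_weight(code: int) -> float:
    if not (WEIGHT_FORMAT.min_code <= code <= WEIGHT_FORMAT.max_code):
        raise ConfigError(f"weight code {code} outside the 14-bit range")
    return float(dequantize(int(code), WEIGHT_FORMAT))


@dataclass(frozen=True)
class Synapse:
    """Directed connection: presynaptic id, postsynaptic id, receptor kind,
    14-bit weight code, and a reserved transmission delay (ms, default 0)."""

    pre: int
    post: int
    kind: str
    weight_code: int
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in RECEPTOR_KINDS:
            raise ConfigError(f"unknown receptor kind {self.kind!r}")
        if not (WEIGHT_FORMAT.min_code <= self.weight_code <= WEIGHT_FORMAT.max_code):
            raise ConfigError(f"weight code {self.weight_code} outside the 14-bit range")


@dataclass
class SynapseSet:
    """Weighted, typed directed connections with a global weight factor."""

    entries: list[Synapse] = field(default_factory=list)
    weight_factor: float = 1.0

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.pre, e.post, e.kind)
            if key in seen:
                raise ConfigError(f"duplicate synapse {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def by_kind(self, kind: str) -> list[Synapse]:
        if kind not in RECEPTOR_KINDS:
            raise ConfigError(f"unknown receptor kind {kind!r}")
        return [e for e in self.entries if e.kind == kind]

    def replace_entries(self, entries: list[Synapse]) -> "SynapseSet":
        return SynapseSet(entries=entries, weight_factor=self.weight_factor)
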