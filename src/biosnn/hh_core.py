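"""Hodgkin-Huxley neuron core: gating kinetics, membrane equation, noise.

Single-compartment conductance-based neurons in the Pospischil cortical
formulation: a leak plus up to five voltage-gated currents (fast Na, delayed
rectifier K, slow non-inactivating muscarinic K, and high/low-threshold Ca),
giving the four classic cortical firing classes — fast spiking (FS), regular
spiking (RS), intrinsically bursting (IB) and low-threshold spiking (LTS).
Spontaneous firing is driven by an Ornstein-Uhlenbeck (OU) current emulating
background synaptic bombardment.

Units project-wide: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.

The module also provides a double-precision direct-Euler reference stepper
(:func:`reference_step`, :func:`simulate_neuron`) that evaluates the rate
functions exactly at every step.  It is the numerical oracle against which
the premultiplied-table engine is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GatingSpec",
    "CurrentSpec",
    "OUNoiseParams",
    "NeuronModelParams",
    "NeuronState",
    "RATE_FAMILIES",
    "make_gate",
    "eval_gate_rates",
    "steady_state",
    "gate_step_exact",
    "total_membrane_current",
    "ou_step",
    "ou_stationary_stats",
    "reference_step",
    "simulate_neuron",
    "InstabilityError",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid model or network configuration."""


class InstabilityError(RuntimeError):
    """Numerical blow-up of the membrane integration."""


# --------------------------------------------------------------------------
# gating kinetics


def _trap(x, k):
    """x / (exp(x/k) - 1), continuous at x=0 where the limit is k - x/2."""
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, k - x / 2.0, safe / np.expm1(safe / k))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GatingSpec:
    """One gating variable of a conductance.

    ``formalism`` selects the kinetic form: ``alpha_beta`` supplies opening and
    closing rates (1/ms), ``inf_tau`` a steady state (dimensionless) and a time
    constant (ms).  ``exponent`` is the power of the gate in the conductance
    product; ``instantaneous`` pins the gate to its steady state every step.
    """

    name: str
    formalism: str  # "alpha_beta" | "inf_tau"
    exponent: int
    f1: Callable[[float], float]  # alpha or x_inf
    f2: Callable[[float], float]  # beta or tau
    instantaneous: bool = False
    family: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.formalism not in ("alpha_beta", "inf_tau"):
            raise ConfigError(f"gate {self.name!r}: unknown formalism {self.formalism!r}")
        if self.exponent < 0:
            raise ConfigError(f"gate {self.name!r}: exponent must be >= 0")
        if self.instantaneous and self.formalism != "inf_tau":
            raise ConfigError(f"gate {self.name!r}: instantaneous gates use inf_tau")


def eval_gate_rates(spec: GatingSpec, V: float) -> tuple[float, float]:
    """Raw kinetic pair at voltage ``V``: (alpha, beta) or (x_inf, tau)."""
    a, b = spec.f1(V), spec.f2(V)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigError(f"gate {spec.name!r}: non-finite rate at V={V} mV")
    return a, b


def steady_state(spec: GatingSpec, V: float) -> float:
    a, b = eval_gate_rates(spec, V)
    if spec.formalism == "alpha_beta":
        tot = a + b
        return a / tot if tot > 0 else 0.0
    return a


def gate_step_exact(spec: GatingSpec, x: float, V: float, dt: float) -> float:
    """Forward-Euler gate update using exact rate evaluation (no tables).

    Written in the same multiply-add arrangement as the table path
    (x' = r1*x + r2) so that for constant rates the two are bit-identical.
    """
    a, b = eval_gate_rates(spec, V)
    if spec.formalism == "alpha_beta":
        x = (1.0 - dt * (a + b)) * x + dt * a
    elif spec.instantaneous:
        x = a
    else:
        x = (1.0 - dt / b) * x + dt * a / b
    return min(1.0, max(0.0, x))


# Parametric rate-function families of the Pospischil cortical model.  V_T
# shifts the Na/Kd activation to set the spike threshold; tau_max scales the
# muscarinic K kinetics; Vx shifts the T-type Ca current.  All families return
# (alpha, beta) for alpha_beta gates or (x_inf, tau) for inf_tau gates.


def _na_m(V_T: float):
    return (
        lambda V: 0.32 * _trap(-(V - V_T - 13.0), 4.0),
        lambda V: 0.28 * _trap(V - V_T - 40.0, 5.0),
    )


def _na_h(V_T: float):
    return (
        lambda V: 0.128 * np.exp(-(V - V_T - 17.0) / 18.0),
        lambda V: 4.0 / (1.0 + np.exp(-(V - V_T - 40.0) / 5.0)),
    )


def _kd_n(V_T: float):
    return (
        lambda V: 0.032 * _trap(-(V - V_T - 15.0), 5.0),
        lambda V: 0.5 * np.exp(-(V - V_T - 10.0) / 40.0),
    )


def _km_p(tau_max: float):
    return (
        lambda V: 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0)),
        lambda V: tau_max / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0)),
    )


def _cal_q():
    return (
        lambda V: 0.055 * _trap(-27.0 - V, 3.8),
        lambda V: 0.94 * np.exp((-75.0 - V) / 17.0),
    )


def _cal_r():
    return (
        lambda V: 0.000457 * np.exp((-13.0 - V) / 50.0),
        lambda V: 0.0065 / (np.exp((-15.0 - V) / 28.0) + 1.0),
    )


def _cat_s(Vx: float):
    # activation is instantaneous; tau is a placeholder never used
    return (
        lambda V: 1.0 / (1.0 + np.exp(-(V + Vx + 57.0) / 6.2)),
        lambda V: np.ones_like(np.asarray(V, dtype=float)) if np.ndim(V) else 1.0,
    )


def _cat_u(Vx: float):
    return (
        lambda V: 1.0 / (1.0 + np.exp((V + Vx + 81.0) / 4.0)),
        lambda V: (
            30.8 + (211.4 + np.exp((V + Vx + 113.2) / 5.0)) / (1.0 + np.exp((V + Vx + 84.0) / 3.2))
        )
        / 3.7,
    )


def _const(alpha: float = 1.0, beta: float = 1.0):
    return (
        lambda V: alpha * np.ones_like(np.asarray(V, dtype=float)) if np.ndim(V) else alpha,
        lambda V: beta * np.ones_like(np.asarray(V, dtype=float)) if np.ndim(V) else beta,
    )


RATE_FAMILIES: dict[str, dict] = {
    "na_m": {"make": _na_m, "formalism": "alpha_beta", "args": ("V_T",)},
    "na_h": {"make": _na_h, "formalism": "alpha_beta", "args": ("V_T",)},
    "kd_n": {"make": _kd_n, "formalism": "alpha_beta", "args": ("V_T",)},
    "km_p": {"make": _km_p, "formalism": "inf_tau", "args": ("tau_max",)},
    "cal_q": {"make": _cal_q, "formalism": "alpha_beta", "args": ()},
    "cal_r": {"make": _cal_r, "formalism": "alpha_beta", "args": ()},
    "cat_s": {"make": _cat_s, "formalism": "inf_tau", "args": ("Vx",), "instantaneous": True},
    "cat_u": {"make": _cat_u, "formalism": "inf_tau", "args": ("Vx",)},
    "const": {"make": _const, "formalism": "alpha_beta", "args": ("alpha", "beta")},
}


def make_gate(name: str, family: str, exponent: int, params: dict | None = None) -> GatingSpec:
    """Instantiate a gate from a named kinetics family (data-driven presets)."""
    if family not in RATE_FAMILIES:
        raise ConfigError(f"unknown kinetics family {family!r}")
    entry = RATE_FAMILIES[family]
    params = dict(params or {})
    try:
        f1, f2 = entry["make"](**{k: params[k] for k in entry["args"] if k in params})
    except TypeError as exc:
        raise ConfigError(
            f"gate {name!r}: family {family!r} needs parameters {entry['args']}: {exc}"
        ) from exc
    return GatingSpec(
        name=name,
        formalism=entry["formalism"],
        exponent=exponent,
        f1=f1,
        f2=f2,
        instantaneous=entry.get("instantaneous", False),
        family=family,
        params=params,
    )


# --------------------------------------------------------------------------
# neuron parameterization


@dataclass(frozen=True)
class OUNoiseParams:
    """Ornstein-Uhlenbeck noise current: mean ``mu`` (uA/cm^2), mean-reversion
    rate ``theta`` (1/ms), diffusion amplitude ``sigma`` (uA/cm^2 ms^-1/2)."""

    mu: float = 0.0
    theta: float = 0.1
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ConfigError("OU noise: theta must be > 0")
        if self.sigma < 0:
            raise ConfigError("OU noise: sigma must be >= 0")


@dataclass(frozen=True)
class CurrentSpec:
    """One voltage-gated conductance: I = g_max * prod(gate^exp) * (V - E_rev)."""

    name: str
    g_max: float
    E_rev: float
    gates: tuple[GatingSpec, ...]

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ConfigError(f"current {self.name!r}: g_max must be >= 0")


@dataclass(frozen=True)
class NeuronModelParams:
    """Full parameterization of one neuron preset."""

    preset_id: str
    C_m: float
    g_leak: float
    E_leak: float
    currents: tuple[CurrentSpec, ...]
    noise: OUNoiseParams = OUNoiseParams()
    spike_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ConfigError("C_m must be > 0")
        if not (1 <= len(self.currents) <= 6):
            raise ConfigError("a neuron carries between 1 and 6 conductance entries")

    @property
    def gate_specs(self) -> tuple[GatingSpec, ...]:
        return tuple(g for c in self.currents for g in c.gates)

    def init_state(self, V0: float | None = None) -> "NeuronState":
        """Resting state with every gate at its steady state for V0."""
        V = self.E_leak if V0 is None else V0
        gates = np.array([steady_state(g, V) for g in self.gate_specs], dtype=np.float64)
        return NeuronState(V=V, gates=gates, I_noise=self.noise.mu)


@dataclass
class NeuronState:
    V: float
    gates: np.ndarray
    I_noise: float = 0.0
    spiked: bool = False

    def copy(self) -> "NeuronState":
        return NeuronState(self.V, self.gates.copy(), self.I_noise, self.spiked)


# --------------------------------------------------------------------------
# membrane equation and noise


def total_membrane_current(
    params: NeuronModelParams,
    state: NeuronState,
    I_syn: float = 0.0,
    I_stim: float = 0.0,
) -> float:
    """Net membrane current (uA/cm^2): ionic terms plus injected currents.

    ``I_syn`` and ``I_stim`` follow the injected-current convention (positive
    depolarizes); receptor currents computed in the ohmic convention must be
    negated by the caller.
    """
    I = -params.g_leak * (state.V - params.E_leak)
    k = 0
    for cur in params.currents:
        gprod = cur.g_max
        for g in cur.gates:
            gprod *= state.gates[k] ** g.exponent
            k += 1
        I -= gprod * (state.V - cur.E_rev)
    return I + state.I_noise + I_syn + I_stim


def ou_step(I: float, p: OUNoiseParams, dt: float, draw: float) -> float:
    """One Euler-Maruyama step of the OU noise current."""
    return I + p.theta * (p.mu - I) * dt + p.sigma * math.sqrt(dt) * draw


def ou_stationary_stats(p: OUNoiseParams) -> tuple[float, float]:
    """Stationary (mean, variance) of the OU process: (mu, sigma^2 / 2 theta)."""
    return p.mu, p.sigma**2 / (2.0 * p.theta)


# --------------------------------------------------------------------------
# double-precision reference stepper (oracle)


def reference_step(
    params: NeuronModelParams,
    state: NeuronState,
    dt: float,
    I_syn: float = 0.0,
    I_stim: float = 0.0,
    draw: float = 0.0,
) -> NeuronState:
    """One exact-rate forward-Euler / Euler-Maruyama step.

    Gate kinetics are evaluated from their rate functions in double precision
    (no tables, no quantization).  Update ordering mirrors the staged
    datapath: gates advance first from V_n, ionic currents are then assembled
    from the new gate values at V_n, and the voltage integrates last; the
    noise current entering the sum is the previous step's sample.
    """
    new = state.copy()
    for k, g in enumerate(params.gate_specs):
        new.gates[k] = gate_step_exact(g, state.gates[k], state.V, dt)
    probe = NeuronState(V=state.V, gates=new.gates, I_noise=state.I_noise)
    I_total = total_membrane_current(params, probe, I_syn=I_syn, I_stim=I_stim)
    new.V = state.V + dt / params.C_m * I_total
    new.I_noise = ou_step(state.I_noise, params.noise, dt, draw)
    if not np.isfinite(new.V) or abs(new.V) > 1000.0:
        raise InstabilityError(f"membrane voltage diverged (V={new.V!r} mV)")
    new.spiked = state.V < params.spike_threshold <= new.V
    return new


def simulate_neuron(
    params: NeuronModelParams,
    duration_ms: float,
    dt: float = 0.03125,
    I_stim: float | Callable[[float], float] = 0.0,
    seed: int | None = None,
    record_V: bool = False,
    V0: float | None = None,
) -> dict:
    """Integrate a single isolated neuron with the reference stepper.

    Returns a dict with ``spike_times`` (ms) and, if requested, the voltage
    trace sampled every step.  With ``seed=None`` the OU noise uses zero draws
    (deterministic); otherwise draws come from a seeded generator.
    """
    n_steps = int(round(duration_ms / dt))
    state = params.init_state(V0)
    rng = np.random.default_rng(seed) if seed is not None else None
    stim_fn = I_stim if callable(I_stim) else (lambda t, a=float(I_stim): a)
    spikes: list[float] = []
    trace = np.empty(n_steps + 1, dtype=np.float64) if record_V else None
    if record_V:
        trace[0] = state.V
    chunk = None
    for n in range(n_steps):
        if rng is not None:
            if chunk is None or n % 4096 == 0:
                chunk = rng.standard_normal(min(4096, n_steps - n))
            draw = chunk[n % 4096]
        else:
            draw = 0.0
        t = n * dt
        state = reference_step(params, state, dt, I_stim=stim_fn(t), draw=draw)
        if state.spiked:
            spikes.append((n + 1) * dt)
        if record_V:
            trace[n + 1] = state.V
    out = {"spike_times": np.asarray(spikes), "dt": dt, "duration_ms": duration_ms}
    if record_V:
        out["V"] = trace
    return out
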