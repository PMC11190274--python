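"""Fixed-step network engine driven by premultiplied rate tables.

Advances the whole network in steps of 31.25 us (0.03125 ms), mirroring the
hardware datapath it emulates.  Per step and per neuron:

1. table lookup at V_n, every gate advanced by one multiply-add,
2. ionic currents assembled from the new gates at V_n (channel math),
3. receptor states driven by the previous step's spikes (one-step
   spike-to-synapse latency) and summed into the synaptic current,
4. membrane voltage integrated by Euler-Maruyama on the accumulator path,
   using the previous step's Ornstein-Uhlenbeck noise sample, which is then
   refreshed,
5. spike detection as a strict upward crossing of the preset threshold.

Neurons sharing a preset are advanced as one vectorized group; synaptic
drive is a sparse matrix-vector product per receptor kind (receptor state
lives per presynaptic neuron, which is exact because every synapse of a given
kind from one neuron shares its kinetics).

Noise determinism: every neuron owns an independent, reproducible draw
stream spawned from the master seed, so trajectories are bit-identical across
repeats and independent of which neurons are monitored.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .hh_core import ConfigError, InstabilityError, steady_state
from .netgen import NetworkConfig
from .numerics import NumericsMode
from .presets import load_preset
from .rate_tables import DEFAULT_DT, build_table
from .synapses import (
    DEFAULT_RECEPTORS,
    ReceptorParams,
    code_to_weight,
    gabab_activation,
    nmda_mg_block,
)

__all__ = [
    "SimulationConfig",
    "StimCommand",
    "SpikeRaster",
    "Simulation",
    "detect_spike",
    "run",
]

_NOISE_CHUNK = 1024  # steps of per-neuron noise drawn at a time


@dataclass
class SimulationConfig:
    dt: float = DEFAULT_DT  # ms
    duration_s: float = 1.0
    numerics: NumericsMode = field(default_factory=NumericsMode)
    master_seed: int | None = 0  # None draws a seed from OS entropy (logged)
    monitored_waveforms: list[int] = field(default_factory=list)
    spike_collection_interval: float = 1.0  # ms, 1-255
    waveform_collection_interval: float = 1.0  # ms
    table_n_entries: int = 2048
    table_vmin: float = -76.0
    table_vmax: float = 52.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration_s <= 0:
            raise ConfigError("dt and duration must be > 0")
        if not (1.0 <= self.spike_collection_interval <= 255.0):
            raise ConfigError("spike collection interval must lie in 1-255 ms")
        if self.waveform_collection_interval < self.dt:
            raise ConfigError("waveform interval must be >= dt")
        if len(self.monitored_waveforms) > 16:
            raise ConfigError("at most 16 monitored waveforms")


@dataclass(frozen=True)
class StimCommand:
    """Constant-current stimulation of one neuron.

    ``amplitude`` is in uA/cm^2 (0.03 mA/cm^2 = 30 uA/cm^2).
    """

    neuron_id: int
    onset_ms: float
    duration_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ConfigError("stimulation duration must be > 0")


@dataclass
class SpikeRaster:
    """Per-neuron sorted spike times in ms over [0, duration_ms]."""

    spike_times: list[np.ndarray]
    duration_ms: float
    n_neurons: int

    def __post_init__(self) -> None:
        if len(self.spike_times) != self.n_neurons:
            raise ConfigError("raster needs one spike-time array per neuron")
        for i, t in enumerate(self.spike_times):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ConfigError(f"neuron {i}: spike times must be strictly increasing")

    @property
    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times))

    def frame_counts(self, interval_ms: float) -> np.ndarray:
        """(n_frames, n_neurons) spike counts per collection interval."""
        n_frames = int(np.ceil(self.duration_ms / interval_ms))
        out = np.zeros((n_frames, self.n_neurons), dtype=np.int64)
        for i, t in enumerate(self.spike_times):
            if len(t):
                idx = np.minimum((t / interval_ms).astype(np.int64), n_frames - 1)
                np.add.at(out[:, i], idx, 1)
        return out

    def population_counts(self, bin_ms: float) -> np.ndarray:
        return self.frame_counts(bin_ms).sum(axis=1)


def detect_spike(V_prev, V_now, threshold) -> np.ndarray | bool:
    """Strict upward threshold crossing: V_prev < threshold <= V_now."""
    out = np.logical_and(
        np.asarray(V_prev) < threshold, np.asarray(V_now) >= threshold
    )
    return bool(out) if out.ndim == 0 else out


class _Group:
    """Neurons sharing a preset, advanced together through shared tables."""

    def __init__(self, preset_id: str, indices: np.ndarray, cfg: SimulationConfig, params=None):
        self.preset_id = preset_id
        self.indices = indices
        self.params = params if params is not None else load_preset(preset_id)
        specs = self.params.gate_specs
        tables = [
            build_table(
                g,
                dt=cfg.dt,
                vmin=cfg.table_vmin,
                vmax=cfg.table_vmax,
                n_entries=cfg.table_n_entries,
            )
            for g in specs
        ]
        self.vmin = cfg.table_vmin
        self.inv_step = cfg.table_n_entries / (cfg.table_vmax - cfg.table_vmin)
        self.n_entries = cfg.table_n_entries
        self.R1 = np.stack([t.r1 for t in tables])  # (G, n_entries)
        self.R2 = np.stack([t.r2 for t in tables])
        # per current: (g_max, E_rev, gate slice, exponents)
        self.currents = []
        k = 0
        for cur in self.params.currents:
            exps = np.array([g.exponent for g in cur.gates], dtype=np.int64)
            self.currents.append((cur.g_max, cur.E_rev, slice(k, k + len(cur.gates)), exps))
            k += len(cur.gates)
        self.X = np.tile(
            np.array(
                [steady_state(g, self.params.E_leak) for g in specs], dtype=np.float64
            )[:, None],
            (1, len(indices)),
        )

    def advance_gates(self, V: np.ndarray) -> None:
        idx = np.clip(((V - self.vmin) * self.inv_step).astype(np.int64), 0, self.n_entries - 1)
        np.clip(self.R1[:, idx] * self.X + self.R2[:, idx], 0.0, 1.0, out=self.X)

    def ionic_current(self, V: np.ndarray) -> np.ndarray:
        p = self.params
        I = -p.g_leak * (V - p.E_leak)
        for g_max, E_rev, sl, exps in self.currents:
            gates = self.X[sl]
            prod = gates[0] ** exps[0]
            for j in range(1, len(exps)):
                prod = prod * gates[j] ** exps[j]
            I = I - g_max * prod * (V - E_rev)
        return I


class Simulation:
    """Incremental network simulation (used directly by the closed loop)."""

    def __init__(
        self,
        network: NetworkConfig,
        config: SimulationConfig | None = None,
        receptor_params: dict[str, ReceptorParams] | None = None,
        preset_params: dict | None = None,
    ):
        """``preset_params`` optionally maps a preset id to a
        :class:`~biosnn.hh_core.NeuronModelParams` overriding the shipped file
        (custom neuron models without touching the preset library)."""
        self.network = network
        self.config = config or SimulationConfig()
        self.numerics = self.config.numerics
        self.receptors = dict(DEFAULT_RECEPTORS)
        if receptor_params:
            self.receptors.update(receptor_params)
        cfg = self.config
        n = network.n_neurons
        self.n = n
        self.dt = cfg.dt
        self.n_steps = int(round(cfg.duration_s * 1000.0 / cfg.dt))
        self.step_index = 0

        preset_ids = np.asarray(network.presets)
        overrides = preset_params or {}
        self.groups = [
            _Group(pid, np.nonzero(preset_ids == pid)[0], cfg, overrides.get(pid))
            for pid in sorted(set(network.presets))
        ]
        self.V = np.empty(n, dtype=np.float64)
        self.threshold = np.empty(n, dtype=np.float64)
        for g in self.groups:
            self.V[g.indices] = g.params.E_leak
            self.threshold[g.indices] = g.params.spike_threshold

        # OU noise, vectorized over neurons with per-neuron streams
        self.mu = np.array([p.mu for p in network.noise])
        self.theta = np.array([p.theta for p in network.noise])
        self.sigma = np.array([p.sigma for p in network.noise])
        self.I_noise = self.mu.copy()
        if cfg.master_seed is None:
            # true-random run: draw the master seed from entropy, keep it
            # for the log so the run stays reproducible after the fact
            self.master_seed = int(np.random.SeedSequence().generate_state(1)[0])
        else:
            self.master_seed = int(cfg.master_seed)
        ss = np.random.SeedSequence(self.master_seed)
        self._noise_rngs = [np.random.default_rng(s) for s in ss.spawn(n)]
        self._noise_chunk = None
        self._chunk_pos = 0

        # synaptic machinery: one state set per receptor kind present
        self.kinds = sorted({e.kind for e in network.synapses.entries})
        self.Wt: dict[str, sparse.csr_matrix] = {}
        self.r_state: dict[str, np.ndarray] = {}
        self.s_state: dict[str, np.ndarray] = {}
        self.pulse: dict[str, np.ndarray] = {}
        wf = network.synapses.weight_factor
        for kind in self.kinds:
            entries = network.synapses.by_kind(kind)
            rows = [e.post for e in entries]
            cols = [e.pre for e in entries]
            vals = [code_to_weight(e.weight_code) * wf for e in entries]
            self.Wt[kind] = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
            self.r_state[kind] = np.zeros(n)
            self.s_state[kind] = np.zeros(n)
            self.pulse[kind] = np.zeros(n)
        self.prev_spikes = np.zeros(n, dtype=bool)

        # stimulation schedule as per-step amplitude deltas
        self._stim_deltas: dict[int, list[tuple[int, float]]] = {}
        self.I_stim = np.zeros(n)

        self.spike_steps: list[list[int]] = [[] for _ in range(n)]
        self._wave_stride = max(1, int(round(cfg.waveform_collection_interval / cfg.dt)))
        self._wave_ids = list(cfg.monitored_waveforms)
        for i in self._wave_ids:
            if not (0 <= i < n):
                raise ConfigError(f"monitored neuron {i} does not exist")
        self.waveforms: list[np.ndarray] = []
        self._record_waveform()

    # -- stimulation ------------------------------------------------------

    def add_stim(self, cmd: StimCommand) -> None:
        if not (0 <= cmd.neuron_id < self.n):
            raise ConfigError(f"stimulation targets missing neuron {cmd.neuron_id}")
        start = int(round(cmd.onset_ms / self.dt))
        stop = start + max(1, int(round(cmd.duration_ms / self.dt)))
        self._stim_deltas.setdefault(start, []).append((cmd.neuron_id, cmd.amplitude))
        self._stim_deltas.setdefault(stop, []).append((cmd.neuron_id, -cmd.amplitude))

    # -- stepping ---------------------------------------------------------

    @property
    def t_ms(self) -> float:
        return self.step_index * self.dt

    def _noise_draw(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0)
        if self._noise_chunk is None or self._chunk_pos >= self._noise_chunk.shape[0]:
            self._noise_chunk = np.stack(
                [g.standard_normal(_NOISE_CHUNK) for g in self._noise_rngs], axis=1
            )
            self._chunk_pos = 0
        draw = self._noise_chunk[self._chunk_pos]
        self._chunk_pos += 1
        return draw

    def step(self) -> np.ndarray:
        """Advance one dt; returns the boolean spike vector of this step."""
        nm = self.numerics
        for nid, amp in self._stim_deltas.pop(self.step_index, []):
            self.I_stim[nid] += amp
        V = self.V

        # gates and ionic currents (channel math path)
        I_ion = np.empty(self.n)
        for g in self.groups:
            Vg = V[g.indices]
            g.advance_gates(Vg)
            if nm.faithful:
                g.X = np.asarray(nm.channel(g.X))
            I_ion[g.indices] = g.ionic_current(Vg)
        if nm.faithful:
            I_ion = np.asarray(nm.channel(I_ion))

        # receptor states driven by last step's spikes; synaptic current
        I_syn = np.zeros(self.n)
        for kind in self.kinds:
            p = self.receptors[kind]
            pulse = self.pulse[kind]
            if self.prev_spikes.any():
                pulse[self.prev_spikes] = p.T_dur
            T = np.where(pulse > 0, p.T_max, 0.0)
            r = self.r_state[kind]
            r_new = r + self.dt * (p.alpha * T * (1.0 - r) - p.beta * r)
            np.clip(r_new, 0.0, 1.0, out=r_new)
            if kind == "GABA_B":
                s = self.s_state[kind]
                s_new = np.maximum(0.0, s + self.dt * (p.K3 * r - p.K4 * s))
                self.s_state[kind] = s_new
                act = gabab_activation(s_new, p.Kd, p.n)
            elif kind == "NMDA":
                act = r_new  # Mg block applied postsynaptically below
            else:
                act = r_new
            self.r_state[kind] = r_new
            np.maximum(pulse - self.dt, 0.0, out=pulse)
            if nm.faithful:
                act = np.asarray(nm.fixed(act, "synapse"))
            drive = self.Wt[kind] @ act
            I_k = drive * p.g_max * (V - p.E_rev)
            if kind == "NMDA":
                I_k = I_k * nmda_mg_block(V, p.Mg)
            I_syn += I_k
        if nm.faithful and self.kinds:
            I_syn = np.asarray(nm.fixed(I_syn, "accumulator"))

        # membrane integration on the accumulator path
        I_noise = self.I_noise
        if nm.faithful:
            I_noise = np.asarray(nm.fixed(I_noise, "noise"))
        I_total = I_ion - I_syn + I_noise + self.I_stim
        if nm.faithful:
            I_total = np.asarray(nm.fixed(I_total, "accumulator"))
        V_new = V + self.dt * I_total  # C_m folded in: all presets use 1 uF/cm^2
        for g in self.groups:
            if g.params.C_m != 1.0:
                V_new[g.indices] = V[g.indices] + self.dt / g.params.C_m * I_total[g.indices]

        if not np.all(np.isfinite(V_new)) or np.any(np.abs(V_new) > 1000.0):
            bad = int(np.argmax(~np.isfinite(V_new) | (np.abs(V_new) > 1000.0)))
            raise InstabilityError(
                f"membrane voltage diverged for neuron {bad} at t={self.t_ms:.3f} ms"
            )

        spikes = detect_spike(V, V_new, self.threshold)
        self.V = V_new
        # refresh noise for the next step
        draw = self._noise_draw()
        self.I_noise = (
            self.I_noise
            + self.theta * (self.mu - self.I_noise) * self.dt
            + self.sigma * np.sqrt(self.dt) * draw
        )
        self.step_index += 1
        if spikes.any():
            for nid in np.nonzero(spikes)[0]:
                self.spike_steps[nid].append(self.step_index)
        self.prev_spikes = spikes
        self._record_waveform()
        return spikes

    def _record_waveform(self) -> None:
        if self._wave_ids and self.step_index % self._wave_stride == 0:
            self.waveforms.append(self.V[self._wave_ids].copy())

    # -- full run ---------------------------------------------------------

    def run(self, stims: list[StimCommand] | None = None) -> tuple[SpikeRaster, dict, dict]:
        for cmd in stims or []:
            self.add_stim(cmd)
        t0 = time.perf_counter()
        for _ in range(self.n_steps - self.step_index):
            self.step()
        wall = time.perf_counter() - t0
        raster = self.raster()
        waves = {
            "neuron_ids": self._wave_ids,
            "interval_ms": self._wave_stride * self.dt,
            "V": np.asarray(self.waveforms) if self._wave_ids else np.empty((0, 0)),
        }
        log = {
            "master_seed": self.master_seed,
            "numerics_mode": self.numerics.mode,
            "saturation_counts": dict(self.numerics.saturation_counts),
            "n_neurons": self.n,
            "n_steps": self.step_index,
            "dt_ms": self.dt,
            "total_spikes": raster.total_spikes,
            "wall_time_s": wall,
        }
        return raster, waves, log

    def raster(self) -> SpikeRaster:
        times = [self.dt * np.asarray(s, dtype=np.float64) for s in self.spike_steps]
        return SpikeRaster(
            spike_times=times,
            duration_ms=self.step_index * self.dt,
            n_neurons=self.n,
        )


def run(
    network: NetworkConfig,
    config: SimulationConfig | None = None,
    stims: list[StimCommand] | None = None,
) -> tuple[SpikeRaster, dict, dict]:
    """Run a complete simulation; returns (raster, waveforms, run log)."""
    return Simulation(network, config).run(stims)
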