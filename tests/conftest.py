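"""Shared fixtures: tiny networks and helper builders used across the suite."""

import numpy as np
import pytest

from biosnn.engine import Simulation, SimulationConfig, StimCommand
from biosnn.hh_core import OUNoiseParams
from biosnn.netgen import NetworkConfig, Placement
from biosnn.synapses import Synapse, SynapseSet

ZERO_NOISE = OUNoiseParams(mu=0.0, theta=0.1, sigma=0.0)

# the study-condition noise used by the network demonstrations
DEMO_NOISE = {"mu": 0.0, "theta": 1.0 / 15.0, "sigma": 0.2}


def single_neuron_network(preset_id: str, noise: OUNoiseParams = ZERO_NOISE) -> NetworkConfig:
    return NetworkConfig(
        placements=[Placement(0, 0.0, 0.0, 0)],
        presets=[preset_id],
        noise=[noise],
        synapses=SynapseSet(),
        master_seed=1,
    )


def two_neuron_network(kind: str = "AMPA", weight_code: int = 4096) -> NetworkConfig:
    """Neuron 0 (RS or FS depending on kind) synapsing onto neuron 1 (RS)."""
    pre_preset = "FS" if kind == "GABA_A" else "RS"
    return NetworkConfig(
        placements=[Placement(0, 0.0, 0.0, 0), Placement(1, 1.0, 0.0, 0)],
        presets=[pre_preset, "RS"],
        noise=[ZERO_NOISE, ZERO_NOISE],
        synapses=SynapseSet(entries=[Synapse(0, 1, kind, weight_code)]),
        master_seed=1,
    )


@pytest.fixture
def rs_network() -> NetworkConfig:
    return single_neuron_network("RS")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def run_single(
    preset_id: str,
    duration_s: float,
    stim: float = 0.0,
    master_seed: int = 1,
    noise: OUNoiseParams = ZERO_NOISE,
    **sim_kwargs,
):
    """Run one isolated neuron through the table engine; returns the raster."""
    net = single_neuron_network(preset_id, noise)
    sim = Simulation(net, SimulationConfig(duration_s=duration_s, master_seed=master_seed, **sim_kwargs))
    if stim:
        sim.add_stim(StimCommand(0, 0.0, duration_s * 1000.0, stim))
    raster, _, _ = sim.run()
    return raster
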