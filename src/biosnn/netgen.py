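"""Network configuration generators: organoid and clustered topologies.

Neurons receive normally distributed XY coordinates around their group center
(one group per organoid or cluster).  Connectivity is drawn independently per
ordered pair from distance-dependent probability rules:

* within a group (both organoid variants, and the intra-cluster kernel of the
  clustered variant), connection probability falls linearly with distance:

      p = p_max * (1 - d / r_org)            (clamped to [0, 1])

* between the two organoids of a "connectoid", connections are promoted on
  the exterior ring — the probability grows with each neuron's distance from
  its own organoid center:

      p = p_max * 1/2 * (d_pre/r_pre + d_post/r_post)    (clamped)

* between clusters of the brain-like clustered variant, a flat probability.

Excitation/inhibition follows the cortical organoid convention: a fixed
fraction of neurons (default 20%) are fast-spiking inhibitory cells emitting
GABA_A synapses; the rest are regular-spiking excitatory cells emitting AMPA
synapses.  The inhibitory count is deterministic (round(ei_ratio * N)) with
seed-shuffled membership, so the configured ratio holds exactly.

The maximum network is 1024 neurons with 2^20 = 1024^2 synapse slots (dense
all-to-all including autapse slots); generation fails with a capacity error
beyond that.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .hh_core import ConfigError, OUNoiseParams
from .synapses import RECEPTOR_KINDS, Synapse, SynapseSet, weight_to_code, code_to_weight

__all__ = [
    "MAX_NEURONS",
    "SYNAPSE_CAPACITY",
    "synapse_capacity",
    "CapacityError",
    "Placement",
    "TopologySpec",
    "NetworkConfig",
    "prob_internal",
    "prob_external",
    "generate",
    "apply_antagonist",
    "save_network",
    "load_network",
    "export_edge_list",
    "export_adjacency_mtx",
]

MAX_NEURONS = 1024
SYNAPSE_CAPACITY = MAX_NEURONS * MAX_NEURONS  # 2**20 slots, autapse slots included

SCHEMA_VERSION = 1

VARIANTS = ("organoid_single", "organoid_connected", "clustered")

# source preset -> emitted receptor kind
PRESET_RECEPTOR = {"RS": "AMPA", "FS": "GABA_A"}


class CapacityError(ConfigError):
    """Synapse count exceeds the 2^20 hardware-mirrored capacity."""


def synapse_capacity(n_neurons: int = MAX_NEURONS) -> int:
    """Dense all-to-all synapse slots for a network of n neurons."""
    return n_neurons * n_neurons


@dataclass(frozen=True)
class Placement:
    neuron_id: int
    x: float
    y: float
    group_id: int


@dataclass
class TopologySpec:
    """Parameters of one generated topology.

    For organoid variants there are ``n_groups`` organoids of ``n_per_group``
    neurons each; ``r_org`` defaults to twice the placement standard deviation
    ``sigma``.  For the clustered variant ``n_clusters`` groups use the same
    close-neighbor internal kernel plus a flat inter-cluster probability.
    """

    variant: str = "organoid_connected"
    n_per_group: int = 512
    n_groups: int = 2
    p_max_internal: float = 0.10
    p_max_external: float = 0.02
    ei_ratio: float = 0.20
    sigma: float = 1.0
    r_org: float | None = None
    centers: list[tuple[float, float]] | None = None
    n_clusters: int = 8
    weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in RECEPTOR_KINDS}
    )
    weight_factor: float = 1.0
    noise_overrides: dict[str, dict] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown topology variant {self.variant!r}")
        for p in (self.p_max_internal, self.p_max_external):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("connection probabilities must lie in [0, 1]")
        if not (0.0 <= self.ei_ratio <= 1.0):
            raise ConfigError("ei_ratio must lie in [0, 1]")
        if self.sigma <= 0:
            raise ConfigError("placement sigma must be > 0")

    @property
    def effective_groups(self) -> int:
        return self.n_clusters if self.variant == "clustered" else self.n_groups

    @property
    def effective_r_org(self) -> float:
        return 2.0 * self.sigma if self.r_org is None else self.r_org

    @property
    def effective_centers(self) -> list[tuple[float, float]]:
        if self.centers is not None:
            if len(self.centers) != self.effective_groups:
                raise ConfigError("centers length must match the group count")
            return [tuple(c) for c in self.centers]
        # groups spaced 8 sigma apart on the x axis ("millimeters apart"
        # relative to an organoid radius of 2 sigma)
        spacing = 8.0 * self.sigma
        return [(spacing * g, 0.0) for g in range(self.effective_groups)]


@dataclass
class NetworkConfig:
    """A fully specified, serializable network: placement, per-neuron preset
    and noise, typed weighted synapses, and the master seed."""

    placements: list[Placement]
    presets: list[str]
    noise: list[OUNoiseParams]
    synapses: SynapseSet
    master_seed: int
    variant: str = "custom"
    centers: list[tuple[float, float]] = field(default_factory=list)
    r_org: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.placements)
        ids = sorted(p.neuron_id for p in self.placements)
        if ids != list(range(n)):
            raise ConfigError("neuron ids must be unique and dense 0..N-1")
        if len(self.presets) != n or len(self.noise) != n:
            raise ConfigError("presets/noise must have one entry per neuron")
        for e in self.synapses.entries:
            if not (0 <= e.pre < n and 0 <= e.post < n):
                raise ConfigError(f"synapse ({e.pre},{e.post}) references missing neurons")
            expected = PRESET_RECEPTOR.get(self.presets[e.pre])
            if expected is not None and e.kind != expected:
                raise ConfigError(
                    f"synapse from {self.presets[e.pre]} neuron {e.pre} must be {expected}"
                )

    @property
    def n_neurons(self) -> int:
        return len(self.placements)

    def positions(self) -> np.ndarray:
        return np.array([(p.x, p.y) for p in self.placements], dtype=np.float64)

    def group_ids(self) -> np.ndarray:
        return np.array([p.group_id for p in self.placements], dtype=np.int64)


def prob_internal(d, r_org: float, p_max: float):
    """Within-group connection probability, linear in distance (clamped)."""
    if r_org <= 0:
        raise ConfigError("r_org must be > 0")
    return np.clip(p_max * (1.0 - np.asarray(d, dtype=np.float64) / r_org), 0.0, 1.0)


def prob_external(d_pre, r_pre: float, d_post, r_post: float, p_max: float):
    """Between-organoid probability, promoting exterior-ring neurons (clamped)."""
    if r_pre <= 0 or r_post <= 0:
        raise ConfigError("organoid radii must be > 0")
    frac = 0.5 * (
        np.asarray(d_pre, dtype=np.float64) / r_pre + np.asarray(d_post, dtype=np.float64) / r_post
    )
    return np.clip(p_max * frac, 0.0, 1.0)


def generate(spec: TopologySpec) -> NetworkConfig:
    """Generate a network configuration; a pure function of spec + seed."""
    rng = np.random.default_rng(spec.seed)
    n_groups = spec.effective_groups
    n = spec.n_per_group * n_groups
    if n > MAX_NEURONS:
        raise CapacityError(f"{n} neurons exceed the {MAX_NEURONS}-neuron capacity")
    centers = spec.effective_centers
    r_org = spec.effective_r_org

    # placement: normal XY around each group center
    xy = np.empty((n, 2), dtype=np.float64)
    group = np.repeat(np.arange(n_groups), spec.n_per_group)
    for g in range(n_groups):
        rows = slice(g * spec.n_per_group, (g + 1) * spec.n_per_group)
        xy[rows] = np.asarray(centers[g]) + spec.sigma * rng.standard_normal(
            (spec.n_per_group, 2)
        )

    # deterministic E/I counts, seed-shuffled membership within each group
    inhibitory = np.zeros(n, dtype=bool)
    n_inh = int(round(spec.ei_ratio * spec.n_per_group))
    for g in range(n_groups):
        members = np.arange(g * spec.n_per_group, (g + 1) * spec.n_per_group)
        inhibitory[rng.permutation(members)[:n_inh]] = True
    presets = ["FS" if i else "RS" for i in inhibitory]

    # pairwise connection probabilities
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    same = group[:, None] == group[None, :]
    probs = np.zeros((n, n), dtype=np.float64)
    probs[same] = prob_internal(dist[same], r_org, spec.p_max_internal)
    if spec.variant == "organoid_connected":
        d_center = np.linalg.norm(xy - np.asarray(centers)[group], axis=1)
        ext = prob_external(
            np.broadcast_to(d_center[:, None], (n, n))[~same],
            r_org,
            np.broadcast_to(d_center[None, :], (n, n))[~same],
            r_org,
            spec.p_max_external,
        )
        probs[~same] = ext
    elif spec.variant == "clustered":
        probs[~same] = spec.p_max_external
    np.fill_diagonal(probs, 0.0)  # generators exclude autapses

    draws = rng.random((n, n))
    pre_idx, post_idx = np.nonzero(draws < probs)
    if len(pre_idx) > SYNAPSE_CAPACITY:
        raise CapacityError(
            f"{len(pre_idx)} synapses exceed the {SYNAPSE_CAPACITY} capacity"
        )

    entries = []
    kind_of = ["GABA_A" if i else "AMPA" for i in inhibitory]
    codes = {k: weight_to_code(w) for k, w in spec.weights.items()}
    for pre, post in zip(pre_idx.tolist(), post_idx.tolist()):
        kind = kind_of[pre]
        entries.append(Synapse(pre=pre, post=post, kind=kind, weight_code=codes[kind]))

    # per-neuron noise from the preset defaults, optionally overridden
    from . import presets as preset_lib

    noise_cache: dict[str, OUNoiseParams] = {}
    for pid in set(presets):
        base = preset_lib.load_preset(pid).noise
        if spec.noise_overrides and pid in spec.noise_overrides:
            ov = spec.noise_overrides[pid]
            base = OUNoiseParams(
                mu=ov.get("mu", base.mu),
                theta=ov.get("theta", base.theta),
                sigma=ov.get("sigma", base.sigma),
            )
        noise_cache[pid] = base
    noise = [noise_cache[p] for p in presets]

    placements = [
        Placement(neuron_id=i, x=float(xy[i, 0]), y=float(xy[i, 1]), group_id=int(group[i]))
        for i in range(n)
    ]
    return NetworkConfig(
        placements=placements,
        presets=presets,
        noise=noise,
        synapses=SynapseSet(entries=entries, weight_factor=spec.weight_factor),
        master_seed=spec.seed,
        variant=spec.variant,
        centers=centers,
        r_org=r_org,
        provenance={
            "generator": "biosnn.netgen",
            "schema_version": SCHEMA_VERSION,
            "spec": {
                "variant": spec.variant,
                "n_per_group": spec.n_per_group,
                "n_groups": n_groups,
                "p_max_internal": spec.p_max_internal,
                "p_max_external": spec.p_max_external,
                "ei_ratio": spec.ei_ratio,
                "sigma": spec.sigma,
                "seed": spec.seed,
            },
        },
    )


def organoid_demo_spec(
    variant: str = "organoid_connected", n_per_group: int = 128, seed: int = 0
) -> TopologySpec:
    """Study conditions of the scaled organoid demonstration.

    Two organoids with the canonical connection rules (internal probability
    peaking at 10%, external at 2%, 20% inhibitory).  At the 128-neuron scale
    the recurrent weights are fixed at AMPA 0.85 / GABA_A 1.4, calibrated so
    that an isolated organoid produces sparse spontaneous network bursts on
    top of ~1 Hz background firing; the connectoid then synchronizes bursts
    across the two organoids while the separated structure does not.
    """
    return TopologySpec(
        variant=variant,
        n_per_group=n_per_group,
        n_groups=2,
        p_max_internal=0.10,
        p_max_external=0.02,
        ei_ratio=0.20,
        weights={"AMPA": 0.85, "GABA_A": 1.4, "NMDA": 0.0, "GABA_B": 0.0},
        seed=seed,
    )


def apply_antagonist(
    config: NetworkConfig, kind: str, inhibition_fraction: float, seed: int = 0
) -> NetworkConfig:
    """Emulate a receptor antagonist by masking synapses of one kind.

    ``inhibition_fraction=1`` removes every synapse of that kind (full
    antagonist, e.g. CNQX for AMPA or bicuculline for GABA_A); intermediate
    fractions remove a random subset, enabling partial-blockade studies.
    The input configuration is left unmodified.
    """
    if kind not in RECEPTOR_KINDS:
        raise ConfigError(f"unknown receptor kind {kind!r}")
    if not (0.0 <= inhibition_fraction <= 1.0):
        raise ConfigError("inhibition_fraction must lie in [0, 1]")
    new = copy.deepcopy(config)
    if inhibition_fraction == 0.0:
        return new
    rng = np.random.default_rng(seed)
    kept = []
    for e in new.synapses.entries:
        if e.kind != kind:
            kept.append(e)
        elif inhibition_fraction < 1.0 and rng.random() >= inhibition_fraction:
            kept.append(e)
    new.synapses = new.synapses.replace_entries(kept)
    new.provenance = dict(new.provenance)
    new.provenance.setdefault("antagonists", []).append(
        {"kind": kind, "fraction": inhibition_fraction, "seed": seed}
    )
    return new


# --------------------------------------------------------------------------
# serialization


def network_to_dict(config: NetworkConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "variant": config.variant,
        "master_seed": config.master_seed,
        "centers": [list(c) for c in config.centers],
        "r_org": config.r_org,
        "neurons": [
            {
                "id": p.neuron_id,
                "x": p.x,
                "y": p.y,
                "group": p.group_id,
                "preset": config.presets[p.neuron_id],
                "noise": {
                    "mu": config.noise[p.neuron_id].mu,
                    "theta": config.noise[p.neuron_id].theta,
                    "sigma": config.noise[p.neuron_id].sigma,
                },
            }
            for p in config.placements
        ],
        "weight_factor": config.synapses.weight_factor,
        "synapses": [
            [e.pre, e.post, e.kind, e.weight_code] for e in config.synapses.entries
        ],
        "provenance": config.provenance,
    }


def network_from_dict(raw: dict) -> NetworkConfig:
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(f"unsupported network schema version {raw.get('schema_version')!r}")
    for key in ("neurons", "synapses", "master_seed"):
        if key not in raw:
            raise ConfigError(f"network config missing field {key!r}")
    neurons = sorted(raw["neurons"], key=lambda d: d["id"])
    placements = [
        Placement(neuron_id=d["id"], x=float(d["x"]), y=float(d["y"]), group_id=int(d["group"]))
        for d in neurons
    ]
    presets = [d["preset"] for d in neurons]
    noise = [
        OUNoiseParams(
            mu=float(d["noise"]["mu"]),
            theta=float(d["noise"]["theta"]),
            sigma=float(d["noise"]["sigma"]),
        )
        for d in neurons
    ]
    entries = [
        Synapse(pre=int(s[0]), post=int(s[1]), kind=s[2], weight_code=int(s[3]))
        for s in raw["synapses"]
    ]
    return NetworkConfig(
        placements=placements,
        presets=presets,
        noise=noise,
        synapses=SynapseSet(entries=entries, weight_factor=float(raw.get("weight_factor", 1.0))),
        master_seed=int(raw["master_seed"]),
        variant=raw.get("variant", "custom"),
        centers=[tuple(c) for c in raw.get("centers", [])],
        r_org=float(raw.get("r_org", 1.0)),
        provenance=raw.get("provenance", {}),
    )


def save_network(config: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(config), fh, indent=1)


def load_network(path) -> NetworkConfig:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def export_edge_list(config: NetworkConfig, path) -> None:
    """Connectivity as CSV rows pre,post,kind,weight_code,weight."""
    with open(path, "w") as fh:
        fh.write("pre,post,kind,weight_code,weight\n")
        for e in config.synapses.entries:
            fh.write(f"{e.pre},{e.post},{e.kind},{e.weight_code},{code_to_weight(e.weight_code)!r}\n")


def export_adjacency_mtx(config: NetworkConfig, path, kind: str | None = None) -> None:
    """Connectivity as a sparse MatrixMarket file of dequantized weights."""
    from scipy import io as spio
    from scipy import sparse

    n = config.n_neurons
    entries = config.synapses.entries if kind is None else config.synapses.by_kind(kind)
    rows = [e.pre for e in entries]
    cols = [e.post for e in entries]
    vals = [code_to_weight(e.weight_code) for e in entries]
    mat = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    spio.mmwrite(str(path), mat)
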