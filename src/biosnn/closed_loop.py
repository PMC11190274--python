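"""Closed-loop burst-triggered stimulation between the SNN and a counterpart.

Mirrors the biohybrid loop topology: spike-count frames stream from both
sides at a 1 ms cadence; a sliding-window network-burst detector runs on each
stream (10 ms for the SNN side, 250 ms for the biological counterpart, the
windows used with the high-density MEA setup this emulates).  A detection on
one side emits exactly one stimulation command to the other side per lockout
window:

* counterpart burst -> SNN: a constant-current pulse (default 3.120 ms,
  30 uA/cm^2 = 0.03 mA/cm^2) to the neurons on the exterior ring of the
  organoid,
* SNN burst -> counterpart: an electrode pulse descriptor (default 500 us,
  500 mV) delivered to the counterpart sink.

The counterpart is any object honouring a two-method contract (below), so a
real device bridge can replace the scripted mock.  All events carry
simulated-time stamps; command latency is configurable and 0 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Simulation, StimCommand
from .hh_core import ConfigError
from .netgen import NetworkConfig

__all__ = [
    "LoopConfig",
    "LoopEventLog",
    "PulseDescriptor",
    "ScriptedCounterpart",
    "exterior_ring_targets",
    "run_loop",
]


@dataclass(frozen=True)
class PulseDescriptor:
    """Electrode pulse sent to the counterpart."""

    duration_us: float = 500.0
    amplitude_mV: float = 500.0


@dataclass
class LoopConfig:
    """Closed-loop detector and stimulation parameters (windows in ms)."""

    snn_window: float = 10.0
    counterpart_window: float = 250.0
    snn_threshold: float = 10.0  # spikes per window; experiment-specific
    counterpart_threshold: float = 10.0
    frame_ms: float = 1.0
    stim_duration_ms: float = 3.120
    stim_amplitude: float = 30.0  # uA/cm^2 (0.03 mA/cm^2)
    exterior_fraction: float = 0.25
    stim_to_counterpart: PulseDescriptor = field(default_factory=PulseDescriptor)
    snn_lockout: float | None = None  # defaults to one window
    counterpart_lockout: float | None = None
    command_latency_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.snn_window <= 0 or self.counterpart_window <= 0:
            raise ConfigError("detector windows must be > 0")
        if (self.snn_lockout or 0) < 0 or (self.counterpart_lockout or 0) < 0:
            raise ConfigError("lockouts must be >= 0")


@dataclass
class LoopEventLog:
    """Timestamped detection/command records for both loop directions."""

    records: list[dict] = field(default_factory=list)

    def append(self, side: str, detection_ms: float, command_ms: float, command: str) -> None:
        if command_ms < detection_ms:
            raise ConfigError("command time cannot precede detection time")
        self.records.append(
            {
                "side": side,
                "detection_ms": detection_ms,
                "command_ms": command_ms,
                "command": command,
            }
        )

    def count(self, side: str | None = None) -> int:
        return len([r for r in self.records if side is None or r["side"] == side])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["side", "detection_ms", "command_ms", "command"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class ScriptedCounterpart:
    """Mock counterpart: replays a fixed per-frame spike-count script and
    records every pulse it receives.  Optionally echoes a stimulation
    artifact into its own stream (the escalation hazard of real setups)."""

    def __init__(self, counts: np.ndarray, artifact_counts: float = 0.0):
        self.counts = np.asarray(counts, dtype=np.float64)
        self.artifact_counts = artifact_counts
        self.received: list[tuple[float, PulseDescriptor]] = []
        self._pending_artifact = 0.0

    def emit_counts(self, frame_index: int) -> float:
        """Population spike count of the given 1-ms frame."""
        base = self.counts[frame_index] if frame_index < len(self.counts) else 0.0
        out = base + self._pending_artifact
        self._pending_artifact = 0.0
        return float(out)

    def receive_pulse(self, t_ms: float, pulse: PulseDescriptor) -> None:
        self.received.append((t_ms, pulse))
        self._pending_artifact = self.artifact_counts


def exterior_ring_targets(config: NetworkConfig, fraction: float = 0.25) -> list[int]:
    """Neurons on the exterior ring of each organoid.

    Per group, selects the round(fraction * n) neurons farthest from the
    group center (deterministic; distance ties broken by id).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ConfigError("fraction must lie in [0, 1]")
    xy = config.positions()
    groups = config.group_ids()
    targets: list[int] = []
    for g in np.unique(groups):
        members = np.nonzero(groups == g)[0]
        if len(members) == 0:
            raise ConfigError(f"organoid {g} is empty")
        center = (
            np.asarray(config.centers[g])
            if g < len(config.centers)
            else xy[members].mean(axis=0)
        )
        d = np.linalg.norm(xy[members] - center, axis=1)
        k = int(round(fraction * len(members)))
        # sort by (-distance, id): farthest first, stable in id
        order = np.lexsort((members, -d))
        targets.extend(int(i) for i in members[order[:k]])
    return sorted(targets)


class _WindowDetector:
    """Online sliding-window threshold detector with lockout."""

    def __init__(self, window_ms: float, frame_ms: float, threshold: float, lockout_ms: float):
        self.w = max(1, int(round(window_ms / frame_ms)))
        self.frame_ms = frame_ms
        self.threshold = threshold
        self.lockout_ms = lockout_ms
        self.buffer = np.zeros(self.w)
        self.pos = 0
        self.total = 0.0
        self.above_prev = False
        self.lockout_until = -1.0

    def push(self, count: float, t_ms: float) -> bool:
        self.total += count - self.buffer[self.pos]
        self.buffer[self.pos] = count
        self.pos = (self.pos + 1) % self.w
        above = self.total >= self.threshold
        fired = above and not self.above_prev and t_ms > self.lockout_until
        if fired:
            self.lockout_until = t_ms + self.lockout_ms
        self.above_prev = above
        return fired


def run_loop(
    sim: Simulation,
    counterpart,
    cfg: LoopConfig,
    duration_ms: float,
) -> LoopEventLog:
    """Run both loop directions for ``duration_ms`` of simulated time.

    The counterpart contract: ``emit_counts(frame_index) -> float`` at the
    frame cadence, and ``receive_pulse(t_ms, PulseDescriptor)``.
    """
    for name in ("emit_counts", "receive_pulse"):
        if not callable(getattr(counterpart, name, None)):
            raise ConfigError(f"counterpart does not implement {name}()")
    frame_steps = max(1, int(round(cfg.frame_ms / sim.dt)))
    n_frames = int(round(duration_ms / cfg.frame_ms))
    snn_det = _WindowDetector(
        cfg.snn_window,
        cfg.frame_ms,
        cfg.snn_threshold,
        cfg.snn_lockout if cfg.snn_lockout is not None else cfg.snn_window,
    )
    cp_det = _WindowDetector(
        cfg.counterpart_window,
        cfg.frame_ms,
        cfg.counterpart_threshold,
        cfg.counterpart_lockout if cfg.counterpart_lockout is not None else cfg.counterpart_window,
    )
    stim_targets = exterior_ring_targets(sim.network, cfg.exterior_fraction)
    log = LoopEventLog()
    for f in range(n_frames):
        frame_spikes = 0
        for _ in range(frame_steps):
            frame_spikes += int(sim.step().sum())
        t = sim.t_ms
        if snn_det.push(frame_spikes, t):
            cmd_t = t + cfg.command_latency_ms
            counterpart.receive_pulse(cmd_t, cfg.stim_to_counterpart)
            log.append(
                "snn",
                t,
                cmd_t,
                f"pulse {cfg.stim_to_counterpart.duration_us} us "
                f"{cfg.stim_to_counterpart.amplitude_mV} mV",
            )
        if cp_det.push(counterpart.emit_counts(f), t):
            cmd_t = t + cfg.command_latency_ms
            for nid in stim_targets:
                sim.add_stim(
                    StimCommand(
                        neuron_id=nid,
                        onset_ms=cmd_t,
                        duration_ms=cfg.stim_duration_ms,
                        amplitude=cfg.stim_amplitude,
                    )
                )
            log.append(
                "counterpart",
                t,
                cmd_t,
                f"stim {cfg.stim_duration_ms} ms {cfg.stim_amplitude} uA/cm^2 "
                f"to {len(stim_targets)} exterior neurons",
            )
    return log
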