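"""Spike-raster file formats: bit-packed, cumulative-sum and CSV.

The two binary encodings mirror the monitoring stream formats of the hardware
platform this simulator emulates:

* bit-packed (``.bspk``): one bit per neuron per collection interval, set when
  the neuron fired at least once in that interval.  Neurons pack little-endian
  within bytes (neuron 0 -> bit 0), frames are concatenated.  Occupancy is
  preserved exactly but multiple spikes per interval alias to one.
* cumulative (``.cspk``): per frame, the running per-neuron spike count as
  little-endian uint32, which preserves per-frame counts exactly.
* CSV (``.csv``): ``neuron_id,time_ms`` rows — a lossless round trip.

The hardware stream carried its framing out of band; files written here
prepend a self-describing little-endian header (magic, version, neuron count,
collection interval, dt, duration).  Binary readers place each spike at the
start of its frame, so round trips are exact up to interval quantization.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .engine import SpikeRaster
from .hh_core import ConfigError

__all__ = ["RasterFileHeader", "write_raster", "read_raster", "FormatError"]

_MAGIC = {"bitpacked": b"BSPK", "cumulative": b"CSPK"}
_VERSION = 1
# magic(4) version(u8) n_neurons(u32) interval(u8) dt(f64) duration(f64), little-endian
_HEADER = struct.Struct("<4sBIBdd")


class FormatError(ConfigError):
    """Malformed or truncated raster file."""


@dataclass(frozen=True)
class RasterFileHeader:
    format: str  # bitpacked | cumulative | csv
    n_neurons: int
    collection_interval: float  # ms
    dt: float  # ms
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.format not in ("bitpacked", "cumulative", "csv"):
            raise ConfigError(f"unknown raster format {self.format!r}")
        if self.format != "csv" and not (1.0 <= self.collection_interval <= 255.0):
            raise ConfigError("collection interval must lie in 1-255 ms")

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.duration / self.collection_interval))


def write_raster(
    raster: SpikeRaster,
    path,
    format: str = "csv",
    interval: float = 1.0,
    dt: float = 0.03125,
) -> None:
    """Write a raster in one of the three formats."""
    header = RasterFileHeader(
        format=format,
        n_neurons=raster.n_neurons,
        collection_interval=interval,
        dt=dt,
        duration=raster.duration_ms,
    )
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# n_neurons={raster.n_neurons}\n")
            fh.write(f"# duration_ms={raster.duration_ms!r}\n")
            fh.write("neuron_id,time_ms\n")
            for nid, train in enumerate(raster.spike_times):
                for t in train:
                    fh.write(f"{nid},{float(t)!r}\n")
        return

    frames = raster.frame_counts(interval)  # (n_frames, n_neurons)
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                _MAGIC[format],
                _VERSION,
                raster.n_neurons,
                int(round(interval)),
                dt,
                raster.duration_ms,
            )
        )
        if format == "bitpacked":
            occupancy = (frames > 0).astype(np.uint8)
            packed = np.packbits(occupancy, axis=1, bitorder="little")
            fh.write(packed.tobytes())
        else:
            cumulative = np.cumsum(frames, axis=0).astype("<u4")
            fh.write(cumulative.tobytes())


def read_raster(path, format: str | None = None) -> tuple[SpikeRaster, RasterFileHeader]:
    """Read a raster file; binary spikes land at their frame start time.

    ``format`` may be omitted for binary files (identified by magic) but is
    required as "csv" for CSV files lacking a binary header.
    """
    if format == "csv" or (format is None and str(path).endswith(".csv")):
        return _read_csv(path)
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise FormatError(f"truncated header at byte {len(head)}")
        magic, version, n_neurons, interval, dt, duration = _HEADER.unpack(head)
        if magic not in _MAGIC.values():
            raise FormatError(f"unrecognized magic {magic!r}")
        if version != _VERSION:
            raise FormatError(f"unsupported version {version}")
        fmt = "bitpacked" if magic == _MAGIC["bitpacked"] else "cumulative"
        header = RasterFileHeader(
            format=fmt,
            n_neurons=n_neurons,
            collection_interval=float(interval),
            dt=dt,
            duration=duration,
        )
        payload = fh.read()
    n_frames = header.n_frames
    if fmt == "bitpacked":
        bytes_per_frame = (n_neurons + 7) // 8
        expected = n_frames * bytes_per_frame
        if len(payload) != expected:
            raise FormatError(
                f"truncated payload at byte {_HEADER.size + len(payload)}: "
                f"expected {expected} payload bytes, got {len(payload)}"
            )
        bits = np.unpackbits(
            np.frombuffer(payload, dtype=np.uint8).reshape(n_frames, bytes_per_frame),
            axis=1,
            bitorder="little",
        )[:, :n_neurons]
        counts = bits.astype(np.int64)
    else:
        expected = n_frames * n_neurons * 4
        if len(payload) != expected:
            raise FormatError(
                f"truncated payload at byte {_HEADER.size + len(payload)}: "
                f"expected {expected} payload bytes, got {len(payload)}"
            )
        cumulative = (
            np.frombuffer(payload, dtype="<u4").reshape(n_frames, n_neurons).astype(np.int64)
        )
        counts = np.diff(cumulative, axis=0, prepend=np.zeros((1, n_neurons), dtype=np.int64))
    trains = []
    for nid in range(n_neurons):
        times = []
        for f in np.nonzero(counts[:, nid])[0]:
            times.extend([f * header.collection_interval] * int(counts[f, nid]))
        trains.append(np.asarray(times, dtype=np.float64))
    # multiple spikes mapped to one frame start would tie; keep counts but
    # strictly-increasing times are only guaranteed for <=1 spike per frame,
    # so nudge ties by one dt each
    for nid, t in enumerate(trains):
        if len(t) > 1:
            for k in range(1, len(t)):
                if t[k] <= t[k - 1]:
                    t[k] = t[k - 1] + dt
    raster = SpikeRaster(spike_times=trains, duration_ms=duration, n_neurons=n_neurons)
    return raster, header


def _read_csv(path) -> tuple[SpikeRaster, RasterFileHeader]:
    by_neuron: dict[int, list[float]] = {}
    meta: dict[str, str] = {}
    max_id = -1
    max_t = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("neuron_id") or not line:
                continue
            nid_s, t_s = line.split(",")
            nid, t = int(nid_s), float(t_s)
            by_neuron.setdefault(nid, []).append(t)
            max_id = max(max_id, nid)
            max_t = max(max_t, t)
    n = int(meta.get("n_neurons", max_id + 1))
    max_t = float(meta.get("duration_ms", max_t))
    trains = [np.asarray(sorted(by_neuron.get(i, [])), dtype=np.float64) for i in range(n)]
    header = RasterFileHeader(
        format="csv", n_neurons=n, collection_interval=1.0, dt=0.03125, duration=max_t
    )
    raster = SpikeRaster(spike_times=trains, duration_ms=max_t, n_neurons=n)
    return raster, header
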