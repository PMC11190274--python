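"""Mixed-precision arithmetic emulation for the hardware-faithful datapath.

The emulated datapath mixes number representations: ion-channel state and
current computations use 32-bit floating point, while the current summation,
synaptic noise, synapses and synaptic weights travel through fixed-point
paths of 32, 25, 18 and 14 bits respectively.  This module provides

* :class:`FixedFormat` — a signed/unsigned Qm.n fixed-point description with
  truncation (floor) rounding and silent saturation,
* :func:`quantize` / :func:`dequantize` — real <-> integer-code conversion,
* :func:`apply_channel_rounding` — round-to-nearest single precision, used on
  the channel/current math path in faithful mode,
* :class:`NumericsMode` — the run-wide switch between ``float64`` (pure double
  precision, the default for desk-scale studies) and ``faithful`` (quantized)
  arithmetic, carrying the named formats and a saturation counter.

The exact Q-splits of the hardware are not public; the defaults below are an
explicit emulation policy chosen to cover the dynamic ranges of the shipped
neuron presets with headroom, and every split can be overridden from the run
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FixedFormat",
    "NumericsMode",
    "quantize",
    "dequantize",
    "apply_channel_rounding",
    "DEFAULT_FORMATS",
]


@dataclass(frozen=True)
class FixedFormat:
    """Signed fixed-point format with ``word_bits`` total and ``frac_bits``
    fractional bits; rounding truncates toward negative infinity and
    out-of-range values saturate to the representable extremes."""

    word_bits: int
    frac_bits: int
    signed: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.frac_bits < self.word_bits <= 64):
            raise ValueError(
                f"need 0 < frac_bits < word_bits <= 64, got "
                f"word_bits={self.word_bits}, frac_bits={self.frac_bits}"
            )

    @property
    def max_code(self) -> int:
        return 2 ** (self.word_bits - 1) - 1 if self.signed else 2**self.word_bits - 1

    @property
    def min_code(self) -> int:
        return -(2 ** (self.word_bits - 1)) if self.signed else 0

    @property
    def resolution(self) -> float:
        return 2.0**-self.frac_bits


# Emulation policy for the unpublished Q-splits (overridable in run configs):
# weights 14-bit/12-frac (range +-2), synapse activations 18-bit/16-frac
# (range +-2), noise path 25-bit/20-frac (range +-16), current accumulator
# 32-bit/20-frac (range +-2048, covering spike-peak ionic currents with
# headroom at ~1e-6 uA/cm^2 resolution).
DEFAULT_FORMATS: dict[str, FixedFormat] = {
    "weight": FixedFormat(14, 12),
    "synapse": FixedFormat(18, 16),
    "noise": FixedFormat(25, 20),
    "accumulator": FixedFormat(32, 20),
}


def quantize(x, fmt: FixedFormat, saturation_counter: list | None = None):
    """Map a real value (scalar or array) to its integer fixed-point code.

    ``code = clamp(floor(x * 2**frac_bits))``.  Saturated samples are counted
    into ``saturation_counter[0]`` when a one-element list is supplied.
    """
    scaled = np.floor(np.asarray(x, dtype=np.float64) * (1 << fmt.frac_bits))
    if saturation_counter is not None:
        n_sat = int(np.count_nonzero((scaled > fmt.max_code) | (scaled < fmt.min_code)))
        saturation_counter[0] += n_sat
    code = np.clip(scaled, fmt.min_code, fmt.max_code).astype(np.int64)
    return int(code) if np.isscalar(x) else code


def dequantize(code, fmt: FixedFormat):
    """Inverse of :func:`quantize` up to the truncation error < 2**-frac_bits."""
    out = np.asarray(code, dtype=np.float64) * fmt.resolution
    return float(out) if np.isscalar(code) else out


def apply_channel_rounding(x):
    """Round to the nearest single-precision value (channel-math emulation).

    Idempotent: a second application is a no-op.
    """
    out = np.asarray(x, dtype=np.float32).astype(np.float64)
    return float(out) if np.isscalar(x) else out


@dataclass
class NumericsMode:
    """Arithmetic mode of a run.

    ``float64`` bypasses all quantization; ``faithful`` applies single-precision
    rounding to channel math and fixed-point truncation/saturation on the
    weight, synapse, noise and accumulator paths.  Saturation events are
    counted per path and reported in the run log.
    """

    mode: str = "float64"
    formats: dict[str, FixedFormat] = field(default_factory=lambda: dict(DEFAULT_FORMATS))
    saturation_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("float64", "faithful"):
            raise ValueError(f"unknown numerics mode {self.mode!r}")
        for name in DEFAULT_FORMATS:
            if name not in self.formats:
                raise ValueError(f"missing fixed-point format {name!r}")
            self.saturation_counts.setdefault(name, 0)

    @property
    def faithful(self) -> bool:
        return self.mode == "faithful"

    def channel(self, x):
        """Channel/current math: 32-bit float rounding in faithful mode."""
        return apply_channel_rounding(x) if self.faithful else x

    def fixed(self, x, path: str):
        """Pass a value through one of the named fixed-point paths."""
        if not self.faithful:
            return x
        fmt = self.formats[path]
        counter = [0]
        out = dequantize(quantize(x, fmt, counter), fmt)
        self.saturation_counts[path] += counter[0]
        return out

    def copy(self) -> "NumericsMode":
        return replace(self, saturation_counts=dict.fromkeys(self.formats, 0))
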