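"""Premultiplied rate tables for table-driven gating updates.

Instead of evaluating the gating rate functions at run time, the solver
precomputes, on a voltage grid, the pair (r1(V), r2(V)) such that one step of
a gate reduces to a single multiply-add:

    x[n+1] = r1(V[n]) * x[n] + r2(V[n])

For alpha/beta kinetics   r1 = 1 - dt*(alpha+beta),  r2 = dt*alpha.
For x_inf/tau kinetics    r1 = 1 - dt/tau,           r2 = dt*x_inf/tau.
Instantaneous gates store r1 = 0, r2 = x_inf so the same multiply-add pins
them to their steady state.

The default grid has 2048 entries spanning -76..52 mV, matching the fixed
block-RAM table of the hardware design this simulator mirrors; size and range
are tunable to trade accuracy against memory.  Lookup is nearest-lower (floor)
index without interpolation — a single memory read — and out-of-range voltages
clamp to the boundary entries.  Table values are evaluated at entry-center
voltages (vmin + (i + 1/2) * step), which makes the lookup a nearest-sample
quantization of V and removes the half-bin rate bias a left-edge evaluation
would accumulate; the rule is fixed so tables are reproducible bit for bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .hh_core import ConfigError, GatingSpec

__all__ = [
    "RateTable",
    "DEFAULT_VMIN",
    "DEFAULT_VMAX",
    "DEFAULT_N_ENTRIES",
    "DEFAULT_DT",
    "build_table",
    "lookup",
    "lookup_index",
    "table_step",
    "write_table_csv",
    "read_table_csv",
]

DEFAULT_VMIN = -76.0
DEFAULT_VMAX = 52.0
DEFAULT_N_ENTRIES = 2048
DEFAULT_DT = 0.03125  # ms (31.25 us)


@dataclass(frozen=True)
class RateTable:
    """Premultiplied (r1, r2) pairs for one gate over a voltage grid."""

    vmin: float
    vmax: float
    n_entries: int
    dt: float
    r1: np.ndarray
    r2: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        if self.vmax <= self.vmin:
            raise ConfigError("rate table: vmax must exceed vmin")
        if self.n_entries < 2:
            raise ConfigError("rate table: n_entries must be >= 2")
        if len(self.r1) != self.n_entries or len(self.r2) != self.n_entries:
            raise ConfigError("rate table: r1/r2 length mismatch with n_entries")
        if not (np.all(np.isfinite(self.r1)) and np.all(np.isfinite(self.r2))):
            raise ConfigError(f"rate table {self.name!r}: non-finite entries")

    @property
    def step(self) -> float:
        return (self.vmax - self.vmin) / self.n_entries

    @property
    def grid(self) -> np.ndarray:
        """Entry-center voltages at which r1/r2 are evaluated."""
        return self.vmin + self.step * (np.arange(self.n_entries) + 0.5)


def build_table(
    spec: GatingSpec,
    dt: float = DEFAULT_DT,
    vmin: float = DEFAULT_VMIN,
    vmax: float = DEFAULT_VMAX,
    n_entries: int = DEFAULT_N_ENTRIES,
) -> RateTable:
    """Tabulate the premultiplied pair of one gate on the voltage grid."""
    if vmax <= vmin:
        raise ConfigError("build_table: vmax must exceed vmin")
    grid = vmin + (vmax - vmin) / n_entries * (np.arange(n_entries) + 0.5)
    a = np.asarray(spec.f1(grid), dtype=np.float64)
    b = np.asarray(spec.f2(grid), dtype=np.float64)
    if a.shape != grid.shape:
        a = np.full_like(grid, float(a))
    if b.shape != grid.shape:
        b = np.full_like(grid, float(b))
    if spec.formalism == "alpha_beta":
        r1 = 1.0 - dt * (a + b)
        r2 = dt * a
    elif spec.instantaneous:
        r1 = np.zeros_like(grid)
        r2 = a
    else:
        if np.any(b <= 0):
            raise ConfigError(f"gate {spec.name!r}: tau <= 0 on the table grid")
        r1 = 1.0 - dt / b
        r2 = dt * a / b
    return RateTable(vmin=vmin, vmax=vmax, n_entries=n_entries, dt=dt, r1=r1, r2=r2, name=spec.name)


def lookup_index(table: RateTable, V) -> np.ndarray | int:
    """Floor index of V on the grid, clamped to [0, n_entries-1]."""
    idx = np.floor((np.asarray(V, dtype=np.float64) - table.vmin) / table.step)
    idx = np.clip(idx, 0, table.n_entries - 1).astype(np.int64)
    return int(idx) if np.isscalar(V) else idx


def lookup(table: RateTable, V) -> tuple:
    """(r1, r2) at the table entry covering voltage V (no interpolation)."""
    idx = lookup_index(table, V)
    return table.r1[idx], table.r2[idx]


def table_step(x, r1, r2):
    """One multiply-add gate update, clamped to [0, 1]."""
    return np.clip(r1 * np.asarray(x, dtype=np.float64) + r2, 0.0, 1.0)


# --------------------------------------------------------------------------
# CSV export / import (inspection and regression fixtures)


def write_table_csv(table: RateTable, path) -> None:
    """Two-column CSV (r1, r2) preceded by a '#'-prefixed header block."""
    header = (
        f"# rate_table v1\n"
        f"# name={table.name}\n"
        f"# vmin={table.vmin!r}\n"
        f"# vmax={table.vmax!r}\n"
        f"# dt={table.dt!r}\n"
        f"# n_entries={table.n_entries}\n"
        f"r1,r2\n"
    )
    body = io.StringIO()
    np.savetxt(body, np.column_stack([table.r1, table.r2]), delimiter=",", fmt="%.17g")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(body.getvalue())


def read_table_csv(path) -> RateTable:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
            elif line and not line.startswith("r1"):
                rows.append([float(v) for v in line.split(",")])
    if not rows:
        raise ConfigError(f"rate table file {path}: no data rows")
    arr = np.asarray(rows, dtype=np.float64)
    return RateTable(
        vmin=float(meta["vmin"]),
        vmax=float(meta["vmax"]),
        n_entries=int(meta["n_entries"]),
        dt=float(meta["dt"]),
        r1=arr[:, 0],
        r2=arr[:, 1],
        name=meta.get("name", ""),
    )
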