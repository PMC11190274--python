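"""Spike-train analytics: bursts, biomarkers, network bursts, grading.

Burst detection uses the string method: a burst is a maximal run of
consecutive spikes whose inter-spike intervals (ISIs) do not exceed
``max_isi`` (default 100 ms) and which contains at least ``min_spikes``
spikes (default 5).

Biomarkers are the standard multi-electrode measures: per-unit Mean Firing
Rate (MFR, spikes/s), Mean Bursting Rate (MBR, bursts/min), Burst Duration
(BD, ms), the inter-spike intervals (ISI, ms) and the inter-burst intervals
(IBI, ms; end-of-burst to start-of-next).

Configuration grading min-max-normalizes the absolute biomarker differences
between each simulated configuration and the biological target:

    grade = 1 - (|diff_i| - min_i |diff_i|) / (max_i |diff_i| - min_i |diff_i|)

so the closest configuration scores 1 and the farthest 0 per biomarker;
configurations are ranked by the (by default unweighted) mean grade across
biomarkers.  Group comparison uses the two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SpikeRaster
from .hh_core import ConfigError

__all__ = [
    "Burst",
    "BiomarkerSet",
    "detect_bursts",
    "biomarkers",
    "detect_network_burst",
    "grade",
    "grade_table",
    "compare_groups",
    "BIOMARKER_NAMES",
]

BIOMARKER_NAMES = ("MFR", "MBR", "BD")


@dataclass(frozen=True)
class Burst:
    start: float  # ms, first spike of the run
    end: float  # ms, last spike of the run
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_bursts(
    train: np.ndarray, max_isi: float = 100.0, min_spikes: int = 5
) -> list[Burst]:
    """String-method burst detection on one sorted spike train (ms)."""
    t = np.asarray(train, dtype=np.float64)
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ConfigError("spike train must be sorted")
    if len(t) < min_spikes:
        return []
    # split at gaps exceeding max_isi; each segment is a maximal string
    gaps = np.nonzero(np.diff(t) > max_isi)[0]
    bounds = np.concatenate([[0], gaps + 1, [len(t)]])
    bursts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= min_spikes:
            bursts.append(Burst(start=float(t[a]), end=float(t[b - 1]), n_spikes=int(b - a)))
    return bursts


@dataclass
class BiomarkerSet:
    """Per-unit biomarker collections for one raster."""

    MFR: np.ndarray  # spikes/s per neuron
    MBR: np.ndarray  # bursts/min per neuron
    BD: np.ndarray  # ms, pooled burst durations
    ISI: np.ndarray  # ms, pooled inter-spike intervals
    IBI: np.ndarray  # ms, pooled end-to-start inter-burst intervals

    def means(self) -> dict[str, float]:
        return {
            "MFR": float(np.mean(self.MFR)) if len(self.MFR) else 0.0,
            "MBR": float(np.mean(self.MBR)) if len(self.MBR) else 0.0,
            "BD": float(np.mean(self.BD)) if len(self.BD) else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("MFR", "spikes/s", self.MFR),
            ("MBR", "bursts/min", self.MBR),
            ("BD", "ms", self.BD),
            ("ISI", "ms", self.ISI),
            ("IBI", "ms", self.IBI),
        ]
        return pd.DataFrame(
            [
                {
                    "biomarker": name,
                    "units": units,
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "median": float(np.median(vals)) if len(vals) else np.nan,
                }
                for name, units, vals in rows
            ]
        )


def biomarkers(
    raster: SpikeRaster,
    max_isi: float = 100.0,
    min_spikes: int = 5,
    per_unit: bool = True,
) -> BiomarkerSet:
    """Compute the biomarker set of a raster.

    MFR is per unit (spikes/s per neuron) by default, matching per-electrode
    violin plots; ``per_unit=False`` instead reports the single network-total
    rate in the MFR slot.
    """
    if raster.duration_ms <= 0:
        raise ConfigError("raster duration must be > 0")
    dur_s = raster.duration_ms / 1000.0
    dur_min = dur_s / 60.0
    mfr, mbr, bd, isi, ibi = [], [], [], [], []
    for train in raster.spike_times:
        mfr.append(len(train) / dur_s)
        bursts = detect_bursts(train, max_isi=max_isi, min_spikes=min_spikes)
        mbr.append(len(bursts) / dur_min)
        bd.extend(b.duration for b in bursts)
        if len(train) > 1:
            isi.extend(np.diff(train))
        for b0, b1 in zip(bursts[:-1], bursts[1:]):
            ibi.append(b1.start - b0.end)
    if not per_unit:
        mfr = [raster.total_spikes / dur_s]
    return BiomarkerSet(
        MFR=np.asarray(mfr, dtype=np.float64),
        MBR=np.asarray(mbr, dtype=np.float64),
        BD=np.asarray(bd, dtype=np.float64),
        ISI=np.asarray(isi, dtype=np.float64),
        IBI=np.asarray(ibi, dtype=np.float64),
    )


def detect_network_burst(
    counts: np.ndarray,
    bin_ms: float,
    window_ms: float,
    threshold: float,
) -> np.ndarray:
    """Network-burst event times from binned population spike counts.

    ``counts`` holds all-neuron spike counts per bin of ``bin_ms``.  A sliding
    window of ``window_ms`` sums the counts; an event fires at each upward
    crossing of ``threshold``, and a lockout of one window length suppresses
    retriggering.  Returns event times (ms, window-end aligned).
    """
    if window_ms < bin_ms:
        raise ConfigError("window must be at least one bin wide")
    counts = np.asarray(counts, dtype=np.float64)
    w = max(1, int(round(window_ms / bin_ms)))
    if len(counts) == 0:
        return np.asarray([])
    sums = np.convolve(counts, np.ones(w), mode="full")[: len(counts)]
    events = []
    above_prev = False
    lockout_until = -1.0
    for i, s in enumerate(sums):
        above = s >= threshold
        t = (i + 1) * bin_ms
        if above and not above_prev and t > lockout_until:
            events.append(t)
            lockout_until = t + window_ms
        above_prev = above
    return np.asarray(events, dtype=np.float64)


def grade(diffs) -> np.ndarray:
    """Min-max grade of absolute biomarker differences across configurations.

    Returns grades in [0, 1]; the configuration with the smallest |diff|
    scores 1, the largest scores 0.  All-equal diffs grade 1 everywhere
    (guarded division).
    """
    d = np.abs(np.asarray(diffs, dtype=np.float64))
    if d.size == 0:
        raise ConfigError("grade needs at least one configuration")
    span = d.max() - d.min()
    if span == 0:
        return np.ones_like(d)
    return 1.0 - (d - d.min()) / span


def grade_table(
    config_biomarkers: dict[str, dict[str, float]],
    target: dict[str, float],
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Grade many configurations against target biomarker values.

    ``config_biomarkers`` maps configuration name -> {biomarker: value}.
    Returns a DataFrame with per-biomarker diffs and grades plus the
    aggregate (weighted mean, default unweighted) grade, sorted best-first.
    """
    names = list(config_biomarkers)
    markers = list(target)
    rows = {name: {} for name in names}
    for m in markers:
        diffs = np.asarray([config_biomarkers[n][m] - target[m] for n in names])
        grades = grade(diffs)
        for n, d, g in zip(names, diffs, grades):
            rows[n][f"diff_{m}"] = d
            rows[n][f"grade_{m}"] = g
    w = {m: 1.0 for m in markers} if weights is None else weights
    wsum = sum(w[m] for m in markers)
    for n in names:
        rows[n]["grade"] = sum(rows[n][f"grade_{m}"] * w[m] for m in markers) / wsum
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return frame.sort_values("grade", ascending=False)


def plot_biomarker_violins(named_sets: dict[str, BiomarkerSet], path) -> None:
    """Violin plots of MFR/MBR/BD distributions for several rasters.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, marker in zip(axes, BIOMARKER_NAMES):
        data = [getattr(bm, marker) for bm in named_sets.values()]
        data = [d if len(d) else np.asarray([0.0]) for d in data]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(named_sets) + 1), list(named_sets), rotation=45)
        unit = {"MFR": "spikes/s", "MBR": "bursts/min", "BD": "ms"}[marker]
        ax.set_title(f"{marker} ({unit})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_grade_radar(frame: pd.DataFrame, path, top_n: int = 6) -> None:
    """Radar plot of per-biomarker grades for the best configurations.

    ``frame`` is the output of :func:`grade_table`; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grade_cols = [c for c in frame.columns if c.startswith("grade_")]
    labels = [c[len("grade_"):] for c in grade_cols]
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False).tolist()
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4.5, 4.5))
    for name, row in frame.head(top_n).iterrows():
        vals = row[grade_cols].to_numpy(dtype=float).tolist()
        ax.plot(angles + angles[:1], vals + vals[:1], label=str(name))
    ax.set_xticks(angles, labels)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def compare_groups(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison; returns (U, p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ConfigError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
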