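"""Hydration-shell assignment and statistics.

Waters are binned by the minimum distance from their oxygen to any solute
heavy atom: primary shell for d <= 3.5 A (ties to the inner shell),
secondary for 3.5 < d <= 10 A, bulk beyond.  On top of the per-frame
assignment the module computes shell counts, residence runs (maximal
stretches of shell occupancy, with an optional gap tolerance), a
Monte-Carlo shell-volume/density estimate, and burn-in-aware cumulative
averages used to smooth every per-frame series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import AnalysisConfig, FrameSeries, SolvatedSystem

__all__ = [
    "ShellAssignment",
    "ResidenceRun",
    "assign_shells",
    "shell_counts",
    "residence_times",
    "shell_density",
    "cumulative_average",
]


@dataclass(frozen=True)
class ShellAssignment:
    frame_index: int
    water_index: int
    min_distance: float
    shell: str  # primary | secondary | bulk


@dataclass(frozen=True)
class ResidenceRun:
    water_index: int
    shell: str
    start_frame: int
    length: int  # frames, inclusive of tolerated interior gaps
    length_time: float  # ps


def _water_min_distances(
    frame: np.ndarray,
    system: SolvatedSystem,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Minimum distance of each water oxygen to any solute heavy atom."""
    heavy_ids = system.solute_heavy_ids
    if not heavy_ids:
        raise ValueError("system has no solute heavy atoms")
    heavy_idx = [system.index_of(i) for i in heavy_ids]
    oxy_idx = [system.index_of(i) for i in system.water_oxygen_ids]
    if not oxy_idx:
        return np.empty(0)
    solute = frame[heavy_idx]
    oxygens = frame[oxy_idx]
    if box is None:
        tree = cKDTree(solute)
        d, _ = tree.query(oxygens)
        return np.asarray(d, dtype=float)
    # orthorhombic minimum image
    delta = oxygens[:, None, :] - solute[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=2)).min(axis=1)


def _shell_of(d: float, config: AnalysisConfig) -> str:
    if d <= config.primary_cutoff:
        return "primary"
    if d <= config.secondary_cutoff:
        return "secondary"
    return "bulk"


def assign_shells(
    frame: np.ndarray,
    system: SolvatedSystem,
    config: AnalysisConfig,
    frame_index: int = 0,
    box: np.ndarray | None = None,
) -> list[ShellAssignment]:
    """Assign every water to a hydration shell for one frame.

    The water position is its oxygen; the reference set is every solute
    non-hydrogen atom.  The boundary convention is closed on the inner
    side: a water at exactly the primary cutoff is primary.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_atoms, 3):
        raise ValueError("frame atom count does not match system")
    dists = _water_min_distances(frame, system, box=box)
    return [
        ShellAssignment(frame_index, wi, float(d), _shell_of(float(d), config))
        for wi, d in enumerate(dists)
    ]


def shell_counts(
    series: FrameSeries,
    system: SolvatedSystem,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-frame water counts in each shell.

    Returns a frame-indexed table with columns time, n_primary,
    n_secondary, n_bulk; the three counts always sum to the number of
    waters.
    """
    rows = []
    for fi in range(series.n_frames):
        dists = _water_min_distances(series.frames[fi], system, box=series.box)
        n_pri = int(np.sum(dists <= config.primary_cutoff))
        n_sec = int(np.sum((dists > config.primary_cutoff) & (dists <= config.secondary_cutoff)))
        n_bulk = len(dists) - n_pri - n_sec
        rows.append((fi, series.times[fi], n_pri, n_sec, n_bulk))
    return pd.DataFrame(rows, columns=["frame", "time", "n_primary", "n_secondary", "n_bulk"])


def residence_times(
    series: FrameSeries,
    system: SolvatedSystem,
    config: AnalysisConfig,
    shell: str = "primary",
    gap_tolerance: int = 0,
) -> tuple[list[ResidenceRun], dict]:
    """Maximal occupancy runs of each water in a shell.

    A run is a maximal stretch of frames in which the water sits in
    ``shell``, allowing interior excursions of at most ``gap_tolerance``
    consecutive frames (gap frames count toward the run length).  Requires
    uniform frame spacing when gaps are merged, since the tolerance is
    frame-based.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if series.n_frames > 1:
        dts = np.diff(series.times)
        uniform = np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9)
        if gap_tolerance > 0 and not uniform:
            raise ValueError("gap merging requires uniform frame spacing")
        dt = float(dts[0]) if uniform else float(np.mean(dts))
    else:
        dt = 0.0

    occupancy = np.zeros((series.n_frames, system.n_waters), dtype=bool)
    for fi in range(series.n_frames):
        dists = _water_min_distances(series.frames[fi], system, box=series.box)
        for wi, d in enumerate(dists):
            occupancy[fi, wi] = _shell_of(float(d), config) == shell

    runs: list[ResidenceRun] = []
    for wi in range(system.n_waters):
        frames = np.flatnonzero(occupancy[:, wi])
        if frames.size == 0:
            continue
        # split into intervals, then merge across tolerated gaps
        breaks = np.flatnonzero(np.diff(frames) > 1)
        intervals = []
        start = frames[0]
        for b in breaks:
            intervals.append((start, frames[b]))
            start = frames[b + 1]
        intervals.append((start, frames[-1]))
        merged = [intervals[0]]
        for s, e in intervals[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= gap_tolerance:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            length = int(e - s + 1)
            runs.append(ResidenceRun(wi, shell, int(s), length, length * dt))

    lengths = np.array([r.length for r in runs], dtype=float)
    summary = {
        "n_runs": len(runs),
        "mean_length": float(lengths.mean()) if runs else 0.0,
        "max_length": int(lengths.max()) if runs else 0,
        "mean_length_time": float(lengths.mean() * dt) if runs else 0.0,
        "lengths": lengths,
    }
    return runs, summary


def shell_density(
    frame: np.ndarray,
    system: SolvatedSystem,
    config: AnalysisConfig,
    shell: str = "primary",
    mc_samples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Water number density of a shell, with a Monte-Carlo volume estimate.

    The shell volume is estimated by rejection sampling in the solute
    bounding box padded by the secondary cutoff: the fraction of uniform
    points whose minimum distance to solute heavy atoms falls in the
    shell's distance band, times the box volume.  The standard error of
    the volume is the binomial error of that fraction.
    """
    if mc_samples < 10_000:
        raise ValueError("mc_samples must be at least 10^4")
    if shell not in ("primary", "secondary"):
        raise ValueError("shell density is defined for primary or secondary")
    frame = np.asarray(frame, dtype=float)
    heavy_idx = [system.index_of(i) for i in system.solute_heavy_ids]
    if not heavy_idx:
        raise ValueError("system has no solute heavy atoms")
    solute = frame[heavy_idx]
    pad = config.secondary_cutoff
    lo = solute.min(axis=0) - pad
    hi = solute.max(axis=0) + pad
    volume_box = float(np.prod(hi - lo))

    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(mc_samples, 3))
    d, _ = cKDTree(solute).query(pts)
    if shell == "primary":
        inside = d <= config.primary_cutoff
    else:
        inside = (d > config.primary_cutoff) & (d <= config.secondary_cutoff)
    p = inside.mean()
    volume = p * volume_box
    volume_se = volume_box * np.sqrt(p * (1 - p) / mc_samples)
    if volume == 0:
        raise ValueError("estimated shell volume is zero; enlarge mc_samples")

    dists = _water_min_distances(frame, system)
    n_shell = int(np.sum([_shell_of(float(x), config) == shell for x in dists]))
    return {
        "shell": shell,
        "n_waters": n_shell,
        "volume": float(volume),
        "volume_se": float(volume_se),
        "density": n_shell / volume,
    }


def cumulative_average(
    values: np.ndarray,
    times: np.ndarray,
    burn_in_time: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Running mean of a per-frame series after discarding burn-in.

    Frames with ``time < burn_in_time`` are dropped; the k-th output is the
    mean of the first k retained values.  Returns (retained_times, means).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ValueError("values and times must have the same length")
    keep = times >= burn_in_time
    if not keep.any():
        raise ValueError("burn-in discards every frame")
    v = values[keep]
    t = times[keep]
    means = np.cumsum(v) / np.arange(1, len(v) + 1)
    return t, means
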