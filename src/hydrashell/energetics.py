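"""Nonbonded interaction energies and trajectory compactness metrics.

The protein-water interaction energy is the pairwise 12-6 Lennard-Jones
plus Coulomb sum over cross pairs within a plain 12 A truncation cutoff,
with Lorentz-Berthelot mixing and the biomolecular Coulomb constant
332.0637 kcal*A/(mol*e^2).  No switching function, no long-range
correction: this mirrors a cutoff-based post-analysis of a trajectory,
not the simulation engine's electrostatics.

Compactness is tracked through the mass-weighted radius of gyration; a
simple baseline-factor rule flags the first frame at which a trajectory
expands beyond a multiple of its early-time Rg (an unfolding onset
detector for heat-denaturation runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .hydration import cumulative_average
from .io_formats import AnalysisConfig, FrameSeries, SolvatedSystem

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "RgSeries",
    "nonbonded_energy",
    "protein_water_energy_series",
    "radius_of_gyration",
    "rg_series",
    "detect_unfolding",
]

#: Coulomb constant in kcal * A / (mol * e^2).
COULOMB_CONSTANT = 332.0637


@dataclass(frozen=True)
class EnergyBreakdown:
    lj: float  # kcal/mol
    coulomb: float  # kcal/mol
    total: float  # kcal/mol
    n_pairs_within_cutoff: int


@dataclass
class RgSeries:
    values: np.ndarray  # A, one per frame
    selection: list[int]
    mass_weighted: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("Rg cannot be negative")


def nonbonded_energy(
    frame: np.ndarray,
    system: SolvatedSystem,
    group_a: list[int],
    group_b: list[int],
    config: AnalysisConfig,
) -> EnergyBreakdown:
    """LJ + Coulomb cross-interaction energy between two disjoint groups.

    E = sum over pairs with r <= cutoff of
    4*eps_ij*((sig_ij/r)^12 - (sig_ij/r)^6) + k_C*q_i*q_j/(eps_r*r),
    sig_ij the arithmetic and eps_ij the geometric mean (Lorentz-Berthelot).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0)
    frame = np.asarray(frame, dtype=float)

    def _params(ids):
        idx, q, sig, eps = [], [], [], []
        for i in ids:
            a = system.atom(i)
            idx.append(system.index_of(i))
            q.append(a.partial_charge)
            sig.append(a.lj_sigma)
            eps.append(a.lj_epsilon)
        return frame[idx], np.array(q), np.array(sig), np.array(eps)

    pos_a, q_a, sig_a, eps_a = _params(group_a)
    pos_b, q_b, sig_b, eps_b = _params(group_b)

    r = cdist(pos_a, pos_b)
    if np.any(r == 0):
        raise ValueError("coincident atoms across groups")
    mask = r <= config.energy_cutoff
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0)

    rm = r[mask]
    sig_ij = (sig_a[:, None] + sig_b[None, :])[mask] / 2.0
    eps_ij = np.sqrt(eps_a[:, None] * eps_b[None, :])[mask]
    sr6 = np.zeros_like(rm)
    nz = eps_ij > 0
    sr6[nz] = (sig_ij[nz] / rm[nz]) ** 6
    lj = float(np.sum(4.0 * eps_ij * (sr6**2 - sr6)))
    coul = float(np.sum(COULOMB_CONSTANT * (q_a[:, None] * q_b[None, :])[mask] / (config.dielectric * rm)))
    return EnergyBreakdown(lj, coul, lj + coul, n_pairs)


def protein_water_energy_series(
    series: FrameSeries,
    system: SolvatedSystem,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Per-frame protein-water interaction energy plus its cumulative average.

    Group A is the solute; group B is every water atom (hydrogens carry
    charge).  Returns the per-frame table and the (times, running-mean)
    pair of the total energy after burn-in.
    """
    water_ids = [i for t in system.water_molecules for i in t]
    rows = []
    for fi in range(series.n_frames):
        e = nonbonded_energy(series.frames[fi], system, system.solute_atom_ids, water_ids, config)
        rows.append((fi, series.times[fi], e.lj, e.coulomb, e.total, e.n_pairs_within_cutoff))
    table = pd.DataFrame(rows, columns=["frame", "time", "lj", "coulomb", "total", "n_pairs"])
    burn_in = config.burn_in_time if (series.times >= config.burn_in_time).any() else 0.0
    cum = cumulative_average(table["total"].to_numpy(), series.times, burn_in)
    return table, cum


def radius_of_gyration(
    frame: np.ndarray,
    selection: list[int] | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration of a selection (unit masses default)."""
    frame = np.asarray(frame, dtype=float)
    pos = frame if selection is None else frame[selection]
    if pos.shape[0] == 0:
        raise ValueError("selection is empty")
    m = np.ones(pos.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * pos).sum(axis=0) / total
    return float(np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / total))


def rg_series(
    series: FrameSeries,
    selection: list[int],
    masses: np.ndarray | None = None,
) -> RgSeries:
    values = [radius_of_gyration(series.frames[fi], selection, masses) for fi in range(series.n_frames)]
    return RgSeries(np.array(values), list(selection), mass_weighted=masses is not None)


def detect_unfolding(
    rg: RgSeries | np.ndarray,
    baseline_window: int,
    factor: float = 1.5,
) -> int | None:
    """First frame at which Rg exceeds ``factor`` times the baseline mean.

    The baseline is the mean Rg over the first ``baseline_window`` frames.
    Returns None when the series never exceeds the threshold.
    """
    values = rg.values if isinstance(rg, RgSeries) else np.asarray(rg, dtype=float)
    if baseline_window < 2:
        raise ValueError("baseline_window must be >= 2")
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    if len(values) < baseline_window:
        raise ValueError("series shorter than baseline window")
    threshold = factor * values[:baseline_window].mean()
    above = np.flatnonzero(values > threshold)
    return int(above[0]) if above.size else None
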