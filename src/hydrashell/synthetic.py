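"""Synthetic solvated systems, trajectories, NMR tables and design sets.

Every analysis stage in this package is validated against data whose
ground truth is known by construction.  This module builds:

* toy solvated systems — a compact cluster of charged pseudo-atoms
  (alternating N/O so each is a hydrogen-bond acceptor, charges +/-0.5 e)
  surrounded by rigid 3-site waters placed at prescribed distances from
  the solute, optionally oriented to donate a perfectly linear or
  deliberately bent hydrogen bond to a chosen solute atom;
* trajectories with frame-by-frame shell occupancy dictated by explicit
  interval patterns, plus truncated Gaussian jitter small enough never to
  cross a shell boundary;
* linear-in-temperature amide chemical-shift series with known slopes;
* exponentially decaying HDX intensity tables with a designated
  protected subset;
* variant sequence sets with an exact, known charged-residue enrichment
  over a template.

Waters carry TIP3P-like charges (O -0.834 e, H +0.417 e) with LJ on the
oxygen only; geometry is the rigid 0.9572 A / 104.52 deg water.  All
generators are deterministic functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AnalysisConfig, AtomRecord, FrameSeries, ObservableTable, SolvatedSystem
from .seqcharge import DesignSet

__all__ = [
    "WaterPlacementSpec",
    "OccupancyPattern",
    "make_toy_system",
    "make_trajectory",
    "make_nmr_tempseries",
    "make_hdx_table",
    "make_design_set",
]

OH_BOND = 0.9572  # A
HOH_ANGLE = 104.52  # deg
WATER_O_CHARGE = -0.834
WATER_H_CHARGE = 0.417
WATER_O_SIGMA = 3.1507
WATER_O_EPSILON = 0.1521
SOLUTE_SIGMA = 3.3
SOLUTE_EPSILON = 0.1
MIN_WATER_SEPARATION = 2.0  # A, oxygen-oxygen


@dataclass(frozen=True)
class WaterPlacementSpec:
    """Where one water goes and whether it donates a hydrogen bond.

    ``hb_geometry`` is ``none``, ``linear`` (O-H points exactly at the
    partner: zero angular deviation) or ``bent`` (the O-H axis is rotated
    ``bent_angle`` degrees off the O->partner line, guaranteeing an
    angular deviation larger than ``bent_angle``).
    """

    shell: str  # primary | secondary | bulk
    target_distance: float  # A to the nearest solute heavy atom
    hb_partner: int | None = None
    hb_geometry: str = "none"  # none | linear | bent
    bent_angle: float | None = None

    def __post_init__(self) -> None:
        if self.shell not in ("primary", "secondary", "bulk"):
            raise ValueError(f"unknown shell {self.shell!r}")
        if self.hb_geometry not in ("none", "linear", "bent"):
            raise ValueError(f"unknown hb_geometry {self.hb_geometry!r}")
        if self.hb_geometry == "bent":
            if self.bent_angle is None or not (0.0 < self.bent_angle < 90.0):
                raise ValueError("bent geometry requires bent_angle in (0, 90) degrees")

    def check_against(self, config: AnalysisConfig) -> None:
        d = self.target_distance
        ok = {
            "primary": d <= config.primary_cutoff,
            "secondary": config.primary_cutoff < d <= config.secondary_cutoff,
            "bulk": d > config.secondary_cutoff,
        }[self.shell]
        if not ok:
            raise ValueError(
                f"target_distance {d} inconsistent with shell {self.shell!r} under active cutoffs"
            )


@dataclass(frozen=True)
class OccupancyPattern:
    """Frame intervals during which one water sits in the primary shell."""

    water_index: int
    frame_intervals: tuple  # of (start, end) inclusive pairs

    def __post_init__(self) -> None:
        ivs = [tuple(int(x) for x in iv) for iv in self.frame_intervals]
        object.__setattr__(self, "frame_intervals", tuple(ivs))
        prev_end = -1
        for s, e in self.frame_intervals:
            if s > e:
                raise ValueError(f"interval ({s}, {e}) is reversed")
            if s <= prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = e

    def occupancy(self, n_frames: int) -> np.ndarray:
        occ = np.zeros(n_frames, dtype=bool)
        for s, e in self.frame_intervals:
            occ[s : e + 1] = True
        return occ


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, u) * u
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about the unit axis."""
    th = np.radians(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1.0 - np.cos(th))
    )


def _solute_lattice(n_solute: int, spacing: float = 2.2) -> np.ndarray:
    """First n points of a cubic lattice ordered by distance from origin."""
    k = 1
    while (2 * k + 1) ** 3 < n_solute:
        k += 1
    grid = np.array(
        [(i, j, l) for i in range(-k, k + 1) for j in range(-k, k + 1) for l in range(-k, k + 1)],
        dtype=float,
    )
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], (grid**2).sum(axis=1)))
    return grid[order[:n_solute]] * spacing


def _water_atoms(
    o_pos: np.ndarray,
    h1_dir: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid 3-site water: O plus two H at the tetrahedral-ish angle."""
    h1 = o_pos + OH_BOND * h1_dir
    axis = _perpendicular(h1_dir, rng)
    h2_dir = _rotate(h1_dir, axis, HOH_ANGLE)
    h2 = o_pos + OH_BOND * h2_dir
    return o_pos, h1, h2


def make_toy_system(
    n_solute: int,
    placements: list[WaterPlacementSpec],
    seed: int,
    config: AnalysisConfig | None = None,
    max_retries: int = 500,
) -> tuple[SolvatedSystem, np.ndarray]:
    """Build a toy solute-plus-waters system with exact shell distances.

    Each water oxygen ends up at exactly its ``target_distance`` from the
    nearest solute heavy atom (the hb_partner when one is named).  Waters
    are kept >= 2 A apart (oxygen-oxygen).  Deterministic for fixed seed.
    """
    if n_solute < 1:
        raise ValueError("n_solute must be >= 1")
    config = config or AnalysisConfig()
    for p in placements:
        p.check_against(config)
        if p.hb_partner is not None and not (0 <= p.hb_partner < n_solute):
            raise ValueError(f"hb_partner {p.hb_partner} is not a solute atom id")

    rng = np.random.default_rng(seed)
    solute_pos = _solute_lattice(n_solute)
    centroid = solute_pos.mean(axis=0)

    water_coords: list[np.ndarray] = []  # (3, 3) per water: O, H1, H2
    for pi, p in enumerate(placements):
        placed = False
        for _ in range(max_retries):
            if p.hb_partner is not None:
                anchor = p.hb_partner
            else:
                anchor = int(rng.integers(n_solute))
            a_pos = solute_pos[anchor]
            outward = a_pos - centroid
            u = rng.standard_normal(3)
            if np.linalg.norm(outward) > 1e-9:
                u = 0.6 * u / np.linalg.norm(u) + _unit(outward)
            u = _unit(u)
            o_pos = a_pos + p.target_distance * u

            d_all = np.linalg.norm(solute_pos - o_pos, axis=1)
            if d_all.argmin() != anchor or abs(d_all.min() - p.target_distance) > 1e-9:
                continue
            if any(
                np.linalg.norm(o_pos - w[0]) < MIN_WATER_SEPARATION for w in water_coords
            ):
                continue

            if p.hb_geometry == "linear":
                h1_dir = -u  # points exactly at the partner
            elif p.hb_geometry == "bent":
                axis = _perpendicular(u, rng)
                h1_dir = _rotate(-u, axis, p.bent_angle)
            else:
                h1_dir = _unit(rng.standard_normal(3))
            water_coords.append(np.stack(_water_atoms(o_pos, h1_dir, rng)))
            placed = True
            break
        if not placed:
            raise ValueError(f"placement {pi} unsatisfiable after {max_retries} retries")

    atoms: list[AtomRecord] = []
    for i, pos in enumerate(solute_pos):
        positive = i % 2 == 0
        atoms.append(
            AtomRecord(
                atom_id=i,
                atom_name="PSN" if positive else "PSO",
                element="N" if positive else "O",
                residue_name="PSD",
                residue_index=i + 1,
                chain_id="A",
                position=pos,
                partial_charge=0.5 if positive else -0.5,
                lj_sigma=SOLUTE_SIGMA,
                lj_epsilon=SOLUTE_EPSILON,
            )
        )
    bonds: list[tuple[int, int]] = []
    waters: list[tuple[int, int, int]] = []
    aid = n_solute
    for wi, coords in enumerate(water_coords):
        o_id, h1_id, h2_id = aid, aid + 1, aid + 2
        res_idx = n_solute + wi + 1
        specs = [
            ("O", "O", WATER_O_CHARGE, WATER_O_SIGMA, WATER_O_EPSILON, False),
            ("H1", "H", WATER_H_CHARGE, 0.0, 0.0, True),
            ("H2", "H", WATER_H_CHARGE, 0.0, 0.0, True),
        ]
        for (name, elem, q, sig, eps, is_h), pos, a_id in zip(
            specs, coords, (o_id, h1_id, h2_id)
        ):
            atoms.append(
                AtomRecord(
                    atom_id=a_id,
                    atom_name=name,
                    element=elem,
                    residue_name="WAT",
                    residue_index=res_idx,
                    chain_id="W",
                    position=pos,
                    partial_charge=q,
                    lj_sigma=sig,
                    lj_epsilon=eps,
                    is_water=True,
                    is_hydrogen=is_h,
                )
            )
        bonds.extend([(o_id, h1_id), (o_id, h2_id)])
        waters.append((o_id, h1_id, h2_id))
        aid += 3

    system = SolvatedSystem(
        atoms=atoms,
        bonds=bonds,
        water_molecules=waters,
        solute_atom_ids=list(range(n_solute)),
    )
    frame0 = system.base_positions()
    return system, frame0


def make_trajectory(
    system: SolvatedSystem,
    patterns: list[OccupancyPattern],
    n_frames: int,
    dt: float = 100.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> FrameSeries:
    """Trajectory whose primary-shell occupancy follows the given patterns.

    Inside a water's intervals its oxygen sits inside the primary shell
    (at its constructed position when that is already primary, otherwise
    at 0.7x the primary cutoff from its nearest solute atom); outside —
    and for every water with no pattern — it is parked beyond the
    secondary cutoff.  The solute is rigid up to jitter; jitter is
    truncated Gaussian (3 sd clip) and refused outright when it could
    cross a shell boundary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    config = config or AnalysisConfig()
    for p in patterns:
        if not (0 <= p.water_index < system.n_waters):
            raise ValueError(f"pattern references missing water {p.water_index}")
        for s, e in p.frame_intervals:
            if e >= n_frames:
                raise ValueError(f"interval ({s}, {e}) exceeds n_frames={n_frames}")
    seen = [p.water_index for p in patterns]
    if len(seen) != len(set(seen)):
        raise ValueError("multiple patterns for one water")

    base = system.base_positions()
    heavy_idx = [system.index_of(i) for i in system.solute_heavy_ids]
    solute = base[heavy_idx]
    oxy_idx = [system.index_of(i) for i in system.water_oxygen_ids]

    d_out = config.secondary_cutoff + 4.0
    in_pos = np.empty((system.n_waters, 3))
    out_pos = np.empty((system.n_waters, 3))
    margins = [d_out - config.secondary_cutoff]
    for wi, oi in enumerate(oxy_idx):
        o = base[oi]
        d = np.linalg.norm(solute - o, axis=1)
        a = d.argmin()
        u = _unit(o - solute[a]) if d[a] > 1e-9 else np.array([1.0, 0.0, 0.0])
        if d[a] <= config.primary_cutoff:
            in_pos[wi] = o
            margins.append(config.primary_cutoff - d[a])
        else:
            in_pos[wi] = solute[a] + 0.7 * config.primary_cutoff * u
            margins.append(0.3 * config.primary_cutoff)
        out_pos[wi] = solute[a] + d_out * u

    if jitter_sd > 0:
        # both endpoints jitter: relative displacement bounded by 2*3sd*sqrt(3)
        max_disp = 2.0 * 3.0 * jitter_sd * np.sqrt(3.0)
        if max_disp >= min(margins):
            raise ValueError(
                f"jitter_sd {jitter_sd} can cross a shell boundary (margin {min(margins):.3f} A)"
            )

    occ = np.zeros((n_frames, system.n_waters), dtype=bool)
    for p in patterns:
        occ[:, p.water_index] = p.occupancy(n_frames)

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, system.n_atoms, 3))
    for fi in range(n_frames):
        coords = base.copy()
        for wi, triple in enumerate(system.water_molecules):
            target_o = in_pos[wi] if occ[fi, wi] else out_pos[wi]
            shift = target_o - base[oxy_idx[wi]]
            for a_id in triple:
                coords[system.index_of(a_id)] += shift
        if jitter_sd > 0:
            noise = np.clip(
                rng.normal(0.0, jitter_sd, size=coords.shape),
                -3.0 * jitter_sd,
                3.0 * jitter_sd,
            )
            coords += noise
        frames[fi] = coords

    times = np.arange(n_frames, dtype=float) * dt
    return FrameSeries(n_atoms=system.n_atoms, frames=frames, times=times)


def make_nmr_tempseries(
    slopes: dict[int, float],
    temperatures: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float | None = None,
) -> ObservableTable:
    """Linear shift-vs-temperature series with known slopes.

    shift(T) = intercept + slope*(T - T0) + noise; slopes are given and
    stored (metadata) in ppb/K, the table carries shifts in ppm and the
    noise sd is in ppb.  Default temperature grid convention follows
    amide-tracking practice: 281-320 K in 5 K increments.
    """
    if len(temperatures) < 3:
        raise ValueError("need at least 3 temperatures")
    t0 = float(t0 if t0 is not None else temperatures[0])
    rng = np.random.default_rng(seed)
    intercepts = {r: 8.0 + 0.5 * rng.standard_normal() for r in sorted(slopes)}
    rows = []
    for r in sorted(slopes):
        for temp in temperatures:
            shift = (
                intercepts[r]
                + slopes[r] / 1000.0 * (temp - t0)
                + rng.normal(0.0, noise_sd / 1000.0)
            )
            rows.append((r, float(temp), shift))
    df = pd.DataFrame(rows, columns=["residue", "temperature_K", "shift_ppm"])
    return ObservableTable(
        kind="tempseries",
        data=df,
        metadata={"slopes_ppb_per_K": dict(slopes), "t0": t0, "intercepts_ppm": intercepts},
    )


def make_hdx_table(
    protected: set[int],
    k_fast: float,
    k_slow: float,
    times: list[float],
    seed: int = 0,
    n_residues: int = 76,
) -> ObservableTable:
    """Exponential HDX intensity decays with a designated protected subset.

    intensity(t) = exp(-k*t) with k = k_slow for protected residues and
    k_fast otherwise.  Residues are 1..n_residues; the membership is the
    stored ground truth.  ``times`` must include 0 (the control spectrum).
    """
    if not (k_fast > k_slow >= 0):
        raise ValueError("require k_fast > k_slow >= 0")
    if not any(np.isclose(t, 0.0) for t in times):
        raise ValueError("times must include 0 (the control spectrum)")
    bad = [r for r in protected if not (1 <= r <= n_residues)]
    if bad:
        raise ValueError(f"protected residues outside 1..{n_residues}: {bad}")
    rows = []
    for r in range(1, n_residues + 1):
        k = k_slow if r in protected else k_fast
        for t in times:
            rows.append((r, float(t), float(np.exp(-k * t))))
    df = pd.DataFrame(rows, columns=["residue", "time_h", "intensity"])
    return ObservableTable(
        kind="hdx",
        data=df,
        metadata={
            "protected": sorted(protected),
            "k_fast_per_h": k_fast,
            "k_slow_per_h": k_slow,
        },
    )


_CHARGED = set("KRDE")


def make_design_set(
    template: str,
    n_variants: int,
    extra_pos: int,
    extra_neg: int,
    seed: int = 0,
) -> DesignSet:
    """Variants enriched by exact numbers of extra charged residues.

    Each variant replaces ``extra_pos`` distinct non-charged template
    positions with K/R and ``extra_neg`` with D/E, all positions chosen
    at random per variant.  The exact per-variant percentage deltas are
    stored as ground truth.
    """
    template = template.upper()
    substitutable = [i for i, c in enumerate(template) if c not in _CHARGED]
    need = extra_pos + extra_neg
    if len(substitutable) < need:
        raise ValueError(
            f"template has only {len(substitutable)} substitutable positions, need {need}"
        )
    rng = np.random.default_rng(seed)
    variants: list[tuple[str, str]] = []
    for vi in range(n_variants):
        chosen = rng.choice(substitutable, size=need, replace=False)
        seq = list(template)
        for pos in chosen[:extra_pos]:
            seq[pos] = "K" if rng.random() < 0.5 else "R"
        for pos in chosen[extra_pos:]:
            seq[pos] = "D" if rng.random() < 0.5 else "E"
        variants.append((f"v{vi + 1:04d}", "".join(seq)))
    n = len(template)
    return DesignSet(
        template=template,
        variants=variants,
        ground_truth={
            "extra_pos": extra_pos,
            "extra_neg": extra_neg,
            "delta_pct_positive": extra_pos / n * 100.0,
            "delta_pct_negative": extra_neg / n * 100.0,
        },
    )
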