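"""Geometric hydrogen-bond detection and classification.

A hydrogen bond is a donor-H...acceptor arrangement with donor-acceptor
distance <= 3.5 A and a deviation of the D-H...A angle from linearity of
<= 30 degrees (i.e. D-H...A >= 150 deg).  Donors are N/O atoms carrying at
least one covalently bound hydrogen; acceptors are all N/O atoms (sulfur
optional).  Detected bonds are classified as protein-water, water-water or
protein-protein, and tagged with the hydration shell of the participating
water so that water-water bonds can be counted per shell.

The distance criterion defaults to heavy-heavy (donor-acceptor) but can be
switched to hydrogen-acceptor via ``AnalysisConfig.hb_distance_mode``; the
angle convention is likewise a declared choice, not a unique truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hydration import _shell_of, _water_min_distances
from .io_formats import AnalysisConfig, FrameSeries, SolvatedSystem

__all__ = [
    "HBondRecord",
    "find_donors_acceptors",
    "detect_hbonds",
    "hbond_counts",
    "per_residue_hbond_map",
]

_DONOR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class HBondRecord:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    da_distance: float  # A (or H-A distance under hydrogen_acceptor mode)
    dha_deviation: float  # degrees from linearity
    hb_class: str  # protein_water | water_water | protein_protein
    shell_context: str  # primary | secondary | other


def find_donors_acceptors(
    system: SolvatedSystem,
    frame: np.ndarray | None = None,
    include_sulfur: bool = False,
) -> tuple[list[tuple[int, list[int]]], list[int]]:
    """Resolve hydrogen-bond donors and acceptors.

    Donors are N/O heavy atoms with >= 1 covalently bound hydrogen;
    acceptors are all N/O atoms.  Hydrogens are attached via the bond
    list when present; an unbonded hydrogen is assigned to the nearest
    heavy atom within 1.2 A (positions from ``frame`` or the stored atom
    coordinates), and an orphan hydrogen is an error.
    """
    elements = _DONOR_ELEMENTS | ({"S"} if include_sulfur else set())
    coords = np.asarray(frame, dtype=float) if frame is not None else system.base_positions()

    h_of: dict[int, list[int]] = {}
    bonded_h = set()
    for a, b in system.bonds:
        ra, rb = system.atom(a), system.atom(b)
        if ra.is_hydrogen and not rb.is_hydrogen:
            h_of.setdefault(b, []).append(a)
            bonded_h.add(a)
        elif rb.is_hydrogen and not ra.is_hydrogen:
            h_of.setdefault(a, []).append(b)
            bonded_h.add(b)

    loose_h = [a.atom_id for a in system.atoms if a.is_hydrogen and a.atom_id not in bonded_h]
    if loose_h:
        heavy = [a for a in system.atoms if not a.is_hydrogen]
        tree = cKDTree(coords[[system.index_of(a.atom_id) for a in heavy]])
        pos = coords[[system.index_of(h) for h in loose_h]]
        d, j = tree.query(pos)
        orphans = [h for h, dd in zip(loose_h, d) if dd > 1.2]
        if orphans:
            raise ValueError(f"hydrogens with no heavy atom within 1.2 A and no bond: {orphans}")
        for h, jj in zip(loose_h, j):
            h_of.setdefault(heavy[jj].atom_id, []).append(h)

    donors = [
        (a.atom_id, sorted(h_of[a.atom_id]))
        for a in system.atoms
        if a.element.upper() in elements and h_of.get(a.atom_id)
    ]
    acceptors = [a.atom_id for a in system.atoms if a.element.upper() in elements]
    return donors, acceptors


def _dha_deviation(d_pos: np.ndarray, h_pos: np.ndarray, a_pos: np.ndarray) -> float:
    """Deviation of the D-H...A angle from 180 degrees."""
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 180.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return 180.0 - float(np.degrees(np.arccos(cosang)))


def detect_hbonds(
    frame: np.ndarray,
    system: SolvatedSystem,
    config: AnalysisConfig,
) -> list[HBondRecord]:
    """All hydrogen bonds in one frame under the geometric criterion.

    Intra-molecular water pairs are excluded; one (donor, acceptor) pair
    yields at most one record (the hydrogen with the smallest angular
    deviation is kept).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_atoms, 3):
        raise ValueError("frame atom count does not match system")
    donors, acceptors = find_donors_acceptors(system, frame, include_sulfur=config.include_sulfur)
    if not donors or not acceptors:
        return []

    acc_idx = np.array([system.index_of(a) for a in acceptors])
    acc_pos = frame[acc_idx]
    tree = cKDTree(acc_pos)

    # shells of every water in this frame, for context labels
    if system.n_waters and system.solute_heavy_ids:
        wdist = _water_min_distances(frame, system)
        water_shell = [_shell_of(float(d), config) for d in wdist]
    else:
        water_shell = ["bulk"] * system.n_waters

    by_id = {a.atom_id: a for a in system.atoms}
    records: dict[tuple[int, int], HBondRecord] = {}
    for d_id, h_ids in donors:
        d_pos = frame[system.index_of(d_id)]
        d_water = system.water_index_of(d_id)
        if config.hb_distance_mode == "donor_acceptor":
            near = tree.query_ball_point(d_pos, config.hb_distance_cutoff)
            candidates = [(a_i, float(np.linalg.norm(acc_pos[a_i] - d_pos))) for a_i in near]
            cand_per_h = {h: candidates for h in h_ids}
        else:  # hydrogen_acceptor
            cand_per_h = {}
            for h in h_ids:
                h_pos = frame[system.index_of(h)]
                near = tree.query_ball_point(h_pos, config.hb_distance_cutoff)
                cand_per_h[h] = [(a_i, float(np.linalg.norm(acc_pos[a_i] - h_pos))) for a_i in near]
        for h in h_ids:
            h_pos = frame[system.index_of(h)]
            for a_i, dist in cand_per_h[h]:
                a_id = int(acceptors[a_i])
                if a_id == d_id:
                    continue
                a_water = system.water_index_of(a_id)
                if d_water is not None and d_water == a_water:
                    continue  # same water molecule
                dev = _dha_deviation(d_pos, h_pos, frame[system.index_of(a_id)])
                if dev > config.hb_angle_cutoff:
                    continue
                donor_is_water = by_id[d_id].is_water
                acceptor_is_water = by_id[a_id].is_water
                if donor_is_water and acceptor_is_water:
                    hb_class = "water_water"
                    context = water_shell[d_water]
                elif donor_is_water or acceptor_is_water:
                    hb_class = "protein_water"
                    w = d_water if donor_is_water else a_water
                    context = water_shell[w]
                else:
                    hb_class = "protein_protein"
                    context = "other"
                if context == "bulk":
                    context = "other"
                rec = HBondRecord(d_id, h, a_id, dist, dev, hb_class, context)
                key = (d_id, a_id)
                if key not in records or dev < records[key].dha_deviation:
                    records[key] = rec
    return sorted(records.values(), key=lambda r: (r.donor_atom, r.acceptor_atom))


def hbond_counts(
    series: FrameSeries,
    system: SolvatedSystem,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-frame counts: total protein-water HBs and water-water HBs per shell."""
    rows = []
    for fi in range(series.n_frames):
        recs = detect_hbonds(series.frames[fi], system, config)
        n_pw = sum(r.hb_class == "protein_water" for r in recs)
        n_ww_pri = sum(r.hb_class == "water_water" and r.shell_context == "primary" for r in recs)
        n_ww_sec = sum(r.hb_class == "water_water" and r.shell_context == "secondary" for r in recs)
        rows.append((fi, series.times[fi], n_pw, n_ww_pri, n_ww_sec))
    return pd.DataFrame(
        rows,
        columns=["frame", "time", "n_protein_water", "n_water_water_primary", "n_water_water_secondary"],
    )


def per_residue_hbond_map(
    series: FrameSeries,
    system: SolvatedSystem,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Mean per-residue HB involvement over retained (post burn-in) frames.

    Protein-water bonds are attributed to the protein residue involved;
    a water-water bond is attributed to every residue with a heavy atom
    within the primary cutoff of either water oxygen.
    """
    keep = series.times >= config.burn_in_time
    if not keep.any():
        keep = np.ones(series.n_frames, dtype=bool)  # short toy runs: no burn-in
    frames = np.flatnonzero(keep)

    water_ids = {i for t in system.water_molecules for i in t}
    residues = sorted(
        {
            (a.chain_id, a.residue_index)
            for a in system.atoms
            if a.atom_id not in water_ids
        }
    )
    res_heavy_idx = {
        res: [
            system.index_of(a.atom_id)
            for a in system.atoms
            if (a.chain_id, a.residue_index) == res and not a.is_hydrogen and a.atom_id not in water_ids
        ]
        for res in residues
    }
    residue_of_atom = {
        a.atom_id: (a.chain_id, a.residue_index) for a in system.atoms if a.atom_id not in water_ids
    }
    oxy_index_of_water = [system.index_of(i) for i in system.water_oxygen_ids]

    pw_sum = {res: 0.0 for res in residues}
    ww_sum = {res: 0.0 for res in residues}
    for fi in frames:
        frame = series.frames[fi]
        for rec in detect_hbonds(frame, system, config):
            if rec.hb_class == "protein_water":
                prot_atom = rec.donor_atom if rec.donor_atom in residue_of_atom else rec.acceptor_atom
                pw_sum[residue_of_atom[prot_atom]] += 1.0
            elif rec.hb_class == "water_water":
                w1 = system.water_index_of(rec.donor_atom)
                w2 = system.water_index_of(rec.acceptor_atom)
                o_pos = frame[[oxy_index_of_water[w1], oxy_index_of_water[w2]]]
                for res in residues:
                    idx = res_heavy_idx[res]
                    if not idx:
                        continue
                    d = np.linalg.norm(frame[idx][:, None, :] - o_pos[None, :, :], axis=2)
                    if (d <= config.primary_cutoff).any():
                        ww_sum[res] += 1.0
    n = len(frames)
    return pd.DataFrame(
        {
            "chain": [r[0] for r in residues],
            "residue": [r[1] for r in residues],
            "mean_protein_water_hb": [pw_sum[r] / n for r in residues],
            "mean_water_water_hb_nearby": [ww_sum[r] / n for r in residues],
        }
    )
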