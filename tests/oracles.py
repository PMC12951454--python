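"""Independent brute-force oracles used across the test suite.

These deliberately re-derive every quantity with plain double/triple
loops and textbook formulas, sharing no code path with the package
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from hydrashell.io_formats import AnalysisConfig, AtomRecord, SolvatedSystem

COULOMB = 332.0637


# ---------------------------------------------------------------------------
# random solvated systems (direct construction, not via the generator)
# ---------------------------------------------------------------------------

def random_solvated_system(
    seed: int,
    n_solute: int = 10,
    n_waters: int = 50,
    box: float = 24.0,
) -> tuple[SolvatedSystem, np.ndarray]:
    """Arbitrary solute pseudo-atoms and rigid waters scattered in a cube."""
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    for i in range(n_solute):
        elem = rng.choice(["N", "O", "C"])
        atoms.append(
            AtomRecord(
                atom_id=i,
                atom_name="PS",
                element=str(elem),
                residue_name="PSD",
                residue_index=i + 1,
                chain_id="A",
                position=rng.uniform(-box / 4, box / 4, 3),
                partial_charge=float(rng.uniform(-0.8, 0.8)),
                lj_sigma=float(rng.uniform(2.8, 3.6)),
                lj_epsilon=float(rng.uniform(0.05, 0.2)),
            )
        )
    bonds, waters = [], []
    aid = n_solute
    for wi in range(n_waters):
        o = rng.uniform(-box / 2, box / 2, 3)
        # rigid water: two O-H arms of 0.9572 A at 104.52 deg
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        p = rng.standard_normal(3)
        p -= np.dot(p, u) * u
        p /= np.linalg.norm(p)
        th = math.radians(104.52)
        v = math.cos(th) * u + math.sin(th) * p
        h1, h2 = o + 0.9572 * u, o + 0.9572 * v
        for name, elem, q, sig, eps, pos, is_h in (
            ("O", "O", -0.834, 3.1507, 0.1521, o, False),
            ("H1", "H", 0.417, 0.0, 0.0, h1, True),
            ("H2", "H", 0.417, 0.0, 0.0, h2, True),
        ):
            atoms.append(
                AtomRecord(
                    atom_id=aid,
                    atom_name=name,
                    element=elem,
                    residue_name="WAT",
                    residue_index=n_solute + wi + 1,
                    chain_id="W",
                    position=pos,
                    partial_charge=q,
                    lj_sigma=sig,
                    lj_epsilon=eps,
                    is_water=True,
                    is_hydrogen=is_h,
                )
            )
            aid += 1
        o_id, h1_id, h2_id = aid - 3, aid - 2, aid - 1
        bonds += [(o_id, h1_id), (o_id, h2_id)]
        waters.append((o_id, h1_id, h2_id))
    system = SolvatedSystem(
        atoms=atoms,
        bonds=bonds,
        water_molecules=waters,
        solute_atom_ids=list(range(n_solute)),
    )
    return system, system.base_positions()


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def shells_bruteforce(
    frame: np.ndarray, system: SolvatedSystem, config: AnalysisConfig
) -> list[tuple[int, float, str]]:
    """(water_index, min_distance, shell) by exhaustive all-pairs distances."""
    heavy = [a for a in system.atoms if a.atom_id in set(system.solute_atom_ids) and not a.is_hydrogen]
    out = []
    for wi, triple in enumerate(system.water_molecules):
        o_id = next(i for i in triple if not system.atom(i).is_hydrogen)
        o = frame[system.index_of(o_id)]
        dmin = min(
            math.dist(o, frame[system.index_of(h.atom_id)]) for h in heavy
        )
        if dmin <= config.primary_cutoff:
            shell = "primary"
        elif dmin <= config.secondary_cutoff:
            shell = "secondary"
        else:
            shell = "bulk"
        out.append((wi, dmin, shell))
    return out


def hbonds_bruteforce(
    frame: np.ndarray, system: SolvatedSystem, config: AnalysisConfig
) -> set[tuple[int, int]]:
    """(donor, acceptor) pairs by exhaustive triple loop over D, H, A."""
    h_of: dict[int, list[int]] = {}
    for a, b in system.bonds:
        ra, rb = system.atom(a), system.atom(b)
        if ra.is_hydrogen and not rb.is_hydrogen:
            h_of.setdefault(b, []).append(a)
        elif rb.is_hydrogen and not ra.is_hydrogen:
            h_of.setdefault(a, []).append(b)
    donors = [
        a.atom_id
        for a in system.atoms
        if a.element in ("N", "O") and h_of.get(a.atom_id)
    ]
    acceptors = [a.atom_id for a in system.atoms if a.element in ("N", "O")]
    water_of = {i: wi for wi, t in enumerate(system.water_molecules) for i in t}
    found = set()
    for d in donors:
        dp = frame[system.index_of(d)]
        for a in acceptors:
            if a == d:
                continue
            if d in water_of and a in water_of and water_of[d] == water_of[a]:
                continue
            ap = frame[system.index_of(a)]
            if math.dist(dp, ap) > config.hb_distance_cutoff:
                continue
            for h in h_of[d]:
                hp = frame[system.index_of(h)]
                v1 = dp - hp
                v2 = ap - hp
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                dev = 180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if dev <= config.hb_angle_cutoff:
                    found.add((d, a))
                    break
    return found


def energy_bruteforce(
    frame: np.ndarray,
    system: SolvatedSystem,
    group_a: list[int],
    group_b: list[int],
    config: AnalysisConfig,
) -> tuple[float, float, int]:
    """(lj, coulomb, n_pairs) by exhaustive pair loop."""
    lj = coul = 0.0
    n = 0
    for i in group_a:
        ai = system.atom(i)
        pi = frame[system.index_of(i)]
        for j in group_b:
            aj = system.atom(j)
            r = math.dist(pi, frame[system.index_of(j)])
            if r > config.energy_cutoff:
                continue
            n += 1
            sig = (ai.lj_sigma + aj.lj_sigma) / 2
            eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            if eps > 0:
                sr6 = (sig / r) ** 6
                lj += 4 * eps * (sr6 * sr6 - sr6)
            coul += COULOMB * ai.partial_charge * aj.partial_charge / (config.dielectric * r)
    return lj, coul, n


def rg_bruteforce(points: np.ndarray, masses: np.ndarray | None = None) -> float:
    m = np.ones(len(points)) if masses is None else masses
    com = sum(mi * p for mi, p in zip(m, points)) / m.sum()
    return math.sqrt(sum(mi * np.dot(p - com, p - com) for mi, p in zip(m, points)) / m.sum())


def runs_from_occupancy(occ: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """(start, length) runs from a boolean series, by interval arithmetic."""
    intervals = []
    start = None
    for i, v in enumerate(occ):
        if v and start is None:
            start = i
        elif not v and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, len(occ) - 1))
    if not intervals:
        return []
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 <= gap_tolerance:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return [(s, e - s + 1) for s, e in merged]
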