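"""Hydrogen-bond detection: geometry rules, classes, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrashell import (
    AnalysisConfig,
    AtomRecord,
    FrameSeries,
    SolvatedSystem,
    WaterPlacementSpec,
    detect_hbonds,
    find_donors_acceptors,
    hbond_counts,
    make_toy_system,
    per_residue_hbond_map,
)
from oracles import hbonds_bruteforce, random_solvated_system


def _atom(i, name, element, res, resname="ALA", water=False, pos=(0, 0, 0)):
    return AtomRecord(
        atom_id=i, atom_name=name, element=element, residue_name=resname,
        residue_index=res, chain_id="A", position=np.array(pos, dtype=float),
        is_water=water, is_hydrogen=element == "H",
    )


def test_water_is_one_donor_two_h_one_acceptor():
    atoms = [
        _atom(0, "O", "O", 1, "WAT", True, (0, 0, 0)),
        _atom(1, "H1", "H", 1, "WAT", True, (0.96, 0, 0)),
        _atom(2, "H2", "H", 1, "WAT", True, (-0.24, 0.93, 0)),
    ]
    system = SolvatedSystem(atoms, [(0, 1), (0, 2)], [(0, 1, 2)], [])
    donors, acceptors = find_donors_acceptors(system)
    assert donors == [(0, [1, 2])]
    assert acceptors == [0]


def test_backbone_amide_and_carbonyl():
    atoms = [
        _atom(0, "N", "N", 1, pos=(0, 0, 0)),
        _atom(1, "H", "H", 1, pos=(1.0, 0, 0)),
        _atom(2, "C", "C", 1, pos=(0, 2, 0)),
        _atom(3, "O", "O", 1, pos=(0, 3.2, 0)),
    ]
    system = SolvatedSystem(atoms, [(0, 1)], [], [0, 1, 2, 3])
    donors, acceptors = find_donors_acceptors(system)
    assert donors == [(0, [1])]
    assert acceptors == [0, 3]


def test_carbon_bound_hydrogen_is_not_a_donor():
    atoms = [
        _atom(0, "CA", "C", 1, pos=(0, 0, 0)),
        _atom(1, "HA", "H", 1, pos=(1.09, 0, 0)),
        _atom(2, "O", "O", 1, pos=(3, 0, 0)),
    ]
    system = SolvatedSystem(atoms, [(0, 1)], [], [0, 1, 2])
    donors, _ = find_donors_acceptors(system)
    assert donors == []


def test_unbonded_hydrogen_resolved_by_proximity_or_error():
    atoms = [
        _atom(0, "N", "N", 1, pos=(0, 0, 0)),
        _atom(1, "H", "H", 1, pos=(1.0, 0, 0)),
    ]
    system = SolvatedSystem(atoms, [], [], [0, 1])
    donors, _ = find_donors_acceptors(system)
    assert donors == [(0, [1])]

    atoms_far = [
        _atom(0, "N", "N", 1, pos=(0, 0, 0)),
        _atom(1, "H", "H", 1, pos=(2.0, 0, 0)),
    ]
    with pytest.raises(ValueError, match="1.2"):
        find_donors_acceptors(SolvatedSystem(atoms_far, [], [], [0, 1]))


def _collinear_system(acceptor_x):
    atoms = [
        _atom(0, "O", "O", 1, "WAT", True, (0, 0, 0)),
        _atom(1, "H1", "H", 1, "WAT", True, (0.96, 0, 0)),
        _atom(2, "H2", "H", 1, "WAT", True, (-0.24, 0.93, 0)),
        _atom(3, "O", "O", 2, "ALA", False, (acceptor_x, 0, 0)),
    ]
    return SolvatedSystem(atoms, [(0, 1), (0, 2)], [(0, 1, 2)], [3])


def test_collinear_construction_detected(config):
    recs = detect_hbonds(
        np.array([a.position for a in _collinear_system(2.8).atoms]),
        _collinear_system(2.8), config,
    )
    assert len(recs) == 1
    r = recs[0]
    assert (r.donor_atom, r.hydrogen_atom, r.acceptor_atom) == (0, 1, 3)
    assert r.da_distance == pytest.approx(2.8)
    assert r.dha_deviation == pytest.approx(0.0, abs=1e-9)
    assert r.hb_class == "protein_water"


def test_distance_rule_rejects_long_bond(config):
    system = _collinear_system(4.0)
    frame = np.array([a.position for a in system.atoms])
    assert detect_hbonds(frame, system, config) == []


@pytest.mark.parametrize("seed", range(6))
def test_detection_matches_triple_loop_oracle(config, seed):
    system, frame = random_solvated_system(seed + 50, n_solute=10, n_waters=50, box=14.0)
    got = {(r.donor_atom, r.acceptor_atom) for r in detect_hbonds(frame, system, config)}
    assert got == hbonds_bruteforce(frame, system, config)


def test_same_pair_through_two_hydrogens_counts_once():
    # both water hydrogens aimed near one acceptor: one record, best H kept
    atoms = [
        _atom(0, "O", "O", 1, "WAT", True, (0, 0, 0)),
        _atom(1, "H1", "H", 1, "WAT", True, (0.96, 0.05, 0)),
        _atom(2, "H2", "H", 1, "WAT", True, (0.96, -0.25, 0)),
        _atom(3, "O", "O", 2, "ALA", False, (2.8, 0, 0)),
    ]
    system = SolvatedSystem(atoms, [(0, 1), (0, 2)], [(0, 1, 2)], [3])
    frame = np.array([a.position for a in atoms])
    recs = detect_hbonds(frame, system, AnalysisConfig())
    assert len(recs) == 1
    assert recs[0].hydrogen_atom == 1  # the straighter hydrogen wins


def test_generator_linear_accepted_bent_rejected(config):
    ok = [WaterPlacementSpec("primary", 2.9, hb_partner=2, hb_geometry="linear")]
    system, frame = make_toy_system(4, ok, seed=1, config=config)
    assert any(r.hb_class == "protein_water" for r in detect_hbonds(frame, system, config))

    bent = [WaterPlacementSpec("primary", 2.9, hb_partner=2, hb_geometry="bent", bent_angle=45.0)]
    system_b, frame_b = make_toy_system(4, bent, seed=1, config=config)
    assert [r for r in detect_hbonds(frame_b, system_b, config)
            if r.hb_class == "protein_water" and r.acceptor_atom == 2] == []


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    d_cut=st.floats(min_value=2.5, max_value=4.5),
    a_cut=st.floats(min_value=10.0, max_value=60.0),
)
def test_counts_monotone_in_both_cutoffs(d_cut, a_cut):
    """Enlarging either cutoff never loses a hydrogen bond."""
    system, frame = random_solvated_system(77, n_solute=8, n_waters=40, box=13.0)
    small = AnalysisConfig(hb_distance_cutoff=d_cut, hb_angle_cutoff=min(a_cut, 89.0))
    big = AnalysisConfig(
        hb_distance_cutoff=d_cut + 0.5, hb_angle_cutoff=min(a_cut + 10.0, 89.9)
    )
    n_small = len(detect_hbonds(frame, system, small))
    n_big = len(detect_hbonds(frame, system, big))
    assert n_big >= n_small


def test_water_water_count_independent_of_enumeration_order(config):
    system, frame = random_solvated_system(31, n_solute=6, n_waters=30, box=12.0)
    recs = detect_hbonds(frame, system, config)
    n_ww = sum(r.hb_class == "water_water" for r in recs)
    # reverse the water list; counts must not change
    system2 = SolvatedSystem(
        atoms=system.atoms,
        bonds=system.bonds,
        water_molecules=list(reversed(system.water_molecules)),
        solute_atom_ids=system.solute_atom_ids,
    )
    recs2 = detect_hbonds(frame, system2, config)
    assert sum(r.hb_class == "water_water" for r in recs2) == n_ww


def test_per_frame_counts_by_construction(config):
    placements = [
        WaterPlacementSpec("primary", 2.8, hb_partner=i, hb_geometry="linear")
        for i in (1, 2, 3)
    ]
    system, frame = make_toy_system(6, placements, seed=3, config=config)
    series = FrameSeries(n_atoms=system.n_atoms, frames=frame[None], times=np.array([0.0]))
    row = hbond_counts(series, system, config).iloc[0]
    assert row.n_protein_water >= 3  # the three constructed bonds, at least


def test_per_residue_map_mean_occupancy(config):
    placements = [WaterPlacementSpec("primary", 2.8, hb_partner=1, hb_geometry="linear")]
    system, frame = make_toy_system(4, placements, seed=4, config=config)
    # two frames: bond present, then water removed far away
    frame2 = frame.copy()
    frame2[4:7] += 100.0  # the water triple sits after 4 solute atoms
    series = FrameSeries(
        n_atoms=system.n_atoms, frames=np.stack([frame, frame2]), times=np.array([0.0, 1.0])
    )
    table = per_residue_hbond_map(series, system, config)
    by_res = table.set_index("residue")["mean_protein_water_hb"]
    assert by_res[2] == pytest.approx(0.5)  # solute atom 1 sits in residue 2
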