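"""Generator ground truth: placements, occupancy patterns, tables, designs."""

import numpy as np
import pytest

from hydrashell import (
    AnalysisConfig,
    OccupancyPattern,
    WaterPlacementSpec,
    assign_shells,
    detect_hbonds,
    make_design_set,
    make_hdx_table,
    make_nmr_tempseries,
    make_toy_system,
    make_trajectory,
    residence_times,
)
from oracles import runs_from_occupancy


def test_primary_placements_assign_as_constructed(config):
    placements = [WaterPlacementSpec("primary", 2.5) for _ in range(5)]
    system, frame = make_toy_system(6, placements, seed=0, config=config)
    shells = [s.shell for s in assign_shells(frame, system, config)]
    assert shells == ["primary"] * 5


def test_placement_distance_exact(config):
    placements = [WaterPlacementSpec("secondary", 7.3), WaterPlacementSpec("primary", 3.2)]
    system, frame = make_toy_system(5, placements, seed=1, config=config)
    for s, want in zip(assign_shells(frame, system, config), (7.3, 3.2)):
        assert abs(s.min_distance - want) < 1e-6


def test_linear_hb_water_detected(config):
    placements = [WaterPlacementSpec("primary", 2.8, hb_partner=2, hb_geometry="linear")]
    system, frame = make_toy_system(4, placements, seed=2, config=config)
    recs = [r for r in detect_hbonds(frame, system, config) if r.hb_class == "protein_water"]
    assert len(recs) == 1
    assert recs[0].acceptor_atom == 2
    assert recs[0].dha_deviation < 1e-5


def test_generator_determinism(config):
    placements = [WaterPlacementSpec("primary", 2.6), WaterPlacementSpec("bulk", 11.0)]
    a = make_toy_system(5, placements, seed=9, config=config)[1]
    b = make_toy_system(5, placements, seed=9, config=config)[1]
    np.testing.assert_array_equal(a, b)


def test_inconsistent_shell_distance_rejected(config):
    with pytest.raises(ValueError, match="inconsistent"):
        make_toy_system(3, [WaterPlacementSpec("primary", 5.0)], seed=0, config=config)


def test_unsatisfiable_placement_errors(config):
    # many waters forced onto one anchor at one exact distance cannot all
    # keep >= 2 A mutual separation
    placements = [
        WaterPlacementSpec("primary", 2.2, hb_partner=2) for _ in range(60)
    ]
    with pytest.raises(ValueError, match="unsatisfiable"):
        make_toy_system(3, placements, seed=0, config=config)


# -- trajectories ------------------------------------------------------------

def test_single_interval_gives_constructed_run(config):
    system, _ = make_toy_system(4, [WaterPlacementSpec("primary", 2.5)], seed=5, config=config)
    series = make_trajectory(
        system, [OccupancyPattern(0, ((10, 50),))], n_frames=100, dt=1.0,
        jitter_sd=0.0, seed=0, config=config,
    )
    runs, _ = residence_times(series, system, config, "primary")
    assert [(r.water_index, r.start_frame, r.length) for r in runs] == [(0, 10, 41)]


def test_empty_patterns_make_all_waters_bulk(config):
    placements = [WaterPlacementSpec("primary", 2.5), WaterPlacementSpec("secondary", 6.0)]
    system, _ = make_toy_system(4, placements, seed=6, config=config)
    series = make_trajectory(system, [], n_frames=10, dt=1.0, seed=0, config=config)
    for fi in range(10):
        assert all(
            s.shell == "bulk" for s in assign_shells(series.frames[fi], system, config)
        )


@pytest.mark.parametrize("gap_tolerance", [0, 1, 3])
def test_disjoint_intervals_match_interval_arithmetic(config, gap_tolerance):
    intervals = ((5, 12), (14, 20), (30, 33))
    system, _ = make_toy_system(4, [WaterPlacementSpec("primary", 2.5)], seed=7, config=config)
    series = make_trajectory(
        system, [OccupancyPattern(0, intervals)], n_frames=40, dt=2.0,
        jitter_sd=0.01, seed=1, config=config,
    )
    runs, _ = residence_times(series, system, config, "primary", gap_tolerance)
    occ = OccupancyPattern(0, intervals).occupancy(40)
    expected = runs_from_occupancy(occ, gap_tolerance)
    assert [(r.start_frame, r.length) for r in runs] == expected
    assert all(abs(r.length_time - r.length * 2.0) < 1e-12 for r in runs)


def test_excessive_jitter_rejected(config):
    system, _ = make_toy_system(4, [WaterPlacementSpec("primary", 2.5)], seed=8, config=config)
    with pytest.raises(ValueError, match="jitter"):
        make_trajectory(
            system, [OccupancyPattern(0, ((0, 5),))], n_frames=6, dt=1.0,
            jitter_sd=1.0, seed=0, config=config,
        )


def test_trajectory_determinism(config):
    system, _ = make_toy_system(4, [WaterPlacementSpec("primary", 2.5)], seed=5, config=config)
    kwargs = dict(n_frames=20, dt=1.0, jitter_sd=0.02, seed=42, config=config)
    a = make_trajectory(system, [OccupancyPattern(0, ((0, 10),))], **kwargs)
    b = make_trajectory(system, [OccupancyPattern(0, ((0, 10),))], **kwargs)
    np.testing.assert_array_equal(a.frames, b.frames)


# -- NMR tables --------------------------------------------------------------

def test_tempseries_stores_ground_truth_and_units():
    temps = list(range(281, 321, 5))
    table = make_nmr_tempseries({7: -5.0}, temps, noise_sd=0.0, seed=0)
    assert table.metadata["slopes_ppb_per_K"] == {7: -5.0}
    got = table.data[table.data["residue"] == 7]
    span = got["shift_ppm"].max() - got["shift_ppm"].min()
    # -5 ppb/K over the 35 K span of the 8-point grid is 0.175 ppm
    assert abs(span - 5.0e-3 * 35) < 1e-12


def test_tempseries_needs_three_temperatures():
    with pytest.raises(ValueError):
        make_nmr_tempseries({1: -3.0}, [281.0, 286.0], seed=0)


def test_hdx_intensities_closed_form():
    table = make_hdx_table({1, 2}, k_fast=1.0, k_slow=0.0, times=[0.0, 48.0], n_residues=4)
    df = table.data.set_index(["residue", "time_h"])["intensity"]
    assert df[(1, 48.0)] == 1.0  # protected, k_slow = 0
    assert abs(df[(3, 48.0)] - np.exp(-48.0)) < 1e-300 or df[(3, 48.0)] < 1e-20


def test_hdx_requires_control_time():
    with pytest.raises(ValueError, match="0"):
        make_hdx_table(set(), 1.0, 0.0, times=[24.0, 48.0])


# -- design sets --------------------------------------------------------------

def test_design_set_exact_deltas():
    template = "G" * 76
    ds = make_design_set(template, 10, extra_pos=4, extra_neg=5, seed=0)
    assert ds.n_variants == 10
    for _vid, seq in ds.variants:
        assert sum(c in "KR" for c in seq) == 4
        assert sum(c in "DE" for c in seq) == 5
        assert len(seq) == 76
    assert abs(ds.ground_truth["delta_pct_positive"] - 4 / 76 * 100) < 1e-12


def test_design_set_determinism_and_emptiness():
    a = make_design_set("G" * 30, 5, 2, 1, seed=3)
    b = make_design_set("G" * 30, 5, 2, 1, seed=3)
    assert a.variants == b.variants
    assert make_design_set("G" * 30, 0, 2, 1, seed=3).n_variants == 0


def test_design_set_insufficient_positions():
    with pytest.raises(ValueError, match="substitutable"):
        make_design_set("KRDE" * 5, 1, extra_pos=1, extra_neg=0, seed=0)
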