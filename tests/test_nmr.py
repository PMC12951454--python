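"""Temperature coefficients, HDX protection, profile correlation, tau_c."""

import numpy as np
import pytest

from hydrashell import (
    RelaxationRecord,
    classify_hbond_from_tempco,
    hdx_protection,
    make_hdx_table,
    make_nmr_tempseries,
    tauc_from_relaxation,
    temp_coefficient,
    tempco_correlation,
)
from hydrashell.nmr import r2_over_r1_for_tauc

TEMPS = list(range(281, 321, 5))  # 281-320 K in 5 K increments


def test_noise_free_slopes_recovered_exactly():
    slopes = {1: -0.64, 2: -5.3, 3: 0.49, 4: 0.33}
    table = make_nmr_tempseries(slopes, TEMPS, noise_sd=0.0, seed=0)
    got = {c.residue: c for c in temp_coefficient(table)}
    for r, s in slopes.items():
        assert got[r].slope == pytest.approx(s, abs=1e-9)
        assert got[r].r_squared == pytest.approx(1.0)
        assert got[r].n_points == len(TEMPS)


def test_constant_shift_gives_zero_slope():
    table = make_nmr_tempseries({5: 0.0}, TEMPS, noise_sd=0.0, seed=0)
    (c,) = temp_coefficient(table)
    assert c.slope == 0.0
    assert c.r_squared == 1.0


def test_short_series_skipped_with_warning():
    table = make_nmr_tempseries({1: -3.0, 2: -4.0}, TEMPS, seed=0)
    table.data = table.data[~((table.data["residue"] == 2) & (table.data["temperature_K"] > 285))]
    with pytest.warns(UserWarning, match="fewer than 3"):
        got = temp_coefficient(table)
    assert [c.residue for c in got] == [1]


def test_monte_carlo_slope_recovery_unbiased():
    """With 5 ppb noise on 8 points the mean recovered slope over 200 seeds
    stays within 0.5 ppb/K of the truth."""
    truth = -3.0
    errs = []
    for seed in range(200):
        table = make_nmr_tempseries({1: truth}, TEMPS, noise_sd=5.0, seed=seed)
        (c,) = temp_coefficient(table)
        errs.append(c.slope - truth)
    assert abs(np.mean(errs)) < 0.5


@pytest.mark.parametrize(
    "slope,threshold,expected",
    [
        (-0.64, -5.0, True),   # strongly hydrogen-bonded amide
        (0.49, -5.0, True),
        (-5.3, -5.0, False),   # solvent-exposed outlier
        (-5.0, -5.0, False),   # boundary: strict inequality
        (-2.0, -2.72, True),
    ],
)
def test_hb_classification_rule(slope, threshold, expected):
    assert classify_hbond_from_tempco(slope, threshold) is expected


# -- correlation ---------------------------------------------------------------

def test_identical_and_affine_profiles_correlate_perfectly():
    a = {i: float(np.sin(i)) for i in range(1, 20)}
    b = {i: 2.0 * v + 3.0 for i, v in a.items()}
    r, n = tempco_correlation(a, a)
    assert r == pytest.approx(1.0)
    r2, n2 = tempco_correlation(a, b)
    assert r2 == pytest.approx(1.0)
    assert n == n2 == 19


def test_correlation_uses_matched_residues_only():
    rng = np.random.default_rng(5)
    shared = rng.standard_normal(30)
    a = {i + 1: float(shared[i] + 0.3 * rng.standard_normal()) for i in range(30)}
    b = {i + 1: float(shared[i] + 0.3 * rng.standard_normal()) for i in range(25)}  # partial overlap
    b[99] = 100.0
    a_extra = dict(a)
    a_extra[150] = -50.0
    r, n = tempco_correlation(a_extra, b)
    assert n == 25
    keys = sorted(set(a) & set(b) - {99, 150})
    manual = np.corrcoef([a[k] for k in keys], [b[k] for k in keys])[0, 1]
    assert r == pytest.approx(manual)


def test_correlation_symmetry_and_bounds():
    rng = np.random.default_rng(6)
    a = {i: float(rng.standard_normal()) for i in range(10)}
    b = {i: float(rng.standard_normal()) for i in range(10)}
    r_ab, _ = tempco_correlation(a, b)
    r_ba, _ = tempco_correlation(b, a)
    assert r_ab == pytest.approx(r_ba)
    assert -1.0 <= r_ab <= 1.0


def test_correlation_needs_three_matches():
    with pytest.raises(ValueError):
        tempco_correlation({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0})


# -- HDX -----------------------------------------------------------------------

def test_fully_retained_signal_protected_everywhere():
    table = make_hdx_table({1}, k_fast=1.0, k_slow=0.0, times=[0.0, 48.0], n_residues=1)
    results, counts = hdx_protection(table, 48.0, thresholds=[0.2, 0.6, 0.99])
    assert results[0].ratio == pytest.approx(1.0)
    assert counts == {0.2: 1, 0.6: 1, 0.99: 1}


def test_unprotected_residue_below_threshold():
    table = make_hdx_table(set(), k_fast=1.0, k_slow=0.0, times=[0.0, 48.0], n_residues=1)
    results, counts = hdx_protection(table, 48.0, thresholds=[0.2])
    assert results[0].ratio < 0.2
    assert counts[0.2] == 0


def test_threshold_inclusivity_conventions():
    """ratio >= 0.2 counts as protected (inclusive); 0.6 is strict."""
    import pandas as pd
    from hydrashell import ObservableTable

    df = pd.DataFrame({
        "residue": [1, 1, 2, 2],
        "time_h": [0.0, 48.0, 0.0, 48.0],
        "intensity": [1.0, 0.2, 1.0, 0.6],
    })
    results, counts = hdx_protection(
        ObservableTable("hdx", df), 48.0, thresholds=[0.2, 0.6]
    )
    by = {r.residue: r for r in results}
    assert by[1].protected_at[0.2] is True     # inclusive at 0.2
    assert by[2].protected_at[0.6] is False    # strict at 0.6
    assert by[2].protected_at[0.2] is True


def test_counts_non_increasing_in_threshold():
    table = make_hdx_table(set(range(1, 31)), 1.0, 0.01, [0.0, 48.0], n_residues=76)
    _, counts = hdx_protection(table, 48.0, thresholds=[0.1, 0.2, 0.4, 0.6, 0.8])
    vals = [counts[t] for t in sorted(counts)]
    assert vals == sorted(vals, reverse=True)


def test_twelve_constructed_slow_exchangers_counted():
    table = make_hdx_table(set(range(1, 13)), k_fast=1.0, k_slow=0.01,
                           times=[0.0, 48.0], n_residues=76)
    _, counts = hdx_protection(table, 48.0, thresholds=[0.2])
    assert counts[0.2] == 12


def test_zero_control_intensity_excluded_with_warning():
    import pandas as pd
    from hydrashell import ObservableTable

    df = pd.DataFrame({
        "residue": [1, 1, 2, 2],
        "time_h": [0.0, 48.0, 0.0, 48.0],
        "intensity": [0.0, 0.5, 1.0, 0.9],
    })
    with pytest.warns(UserWarning, match="excluded"):
        results, _ = hdx_protection(ObservableTable("hdx", df), 48.0)
    assert [r.residue for r in results] == [2]


# -- tau_c ---------------------------------------------------------------------

def test_tauc_round_trip_identity():
    for tau in (4.15, 5.2, 5.5):
        ratio = r2_over_r1_for_tauc(tau, 850.0)
        rec = RelaxationRecord(1, r1=1.2, r2=1.2 * ratio, hetnoe=0.8, field_1H=850.0)
        assert tauc_from_relaxation(rec) == pytest.approx(tau, abs=1e-6)


def test_tauc_domain_error_when_ratio_too_small():
    with pytest.raises(ValueError, match="domain"):
        tauc_from_relaxation(RelaxationRecord(1, r1=2.0, r2=2.0, hetnoe=0.8, field_1H=850.0))


def test_tauc_halves_when_field_doubles():
    rec1 = RelaxationRecord(1, r1=1.0, r2=5.0, hetnoe=0.8, field_1H=600.0)
    rec2 = RelaxationRecord(1, r1=1.0, r2=5.0, hetnoe=0.8, field_1H=1200.0)
    assert tauc_from_relaxation(rec1) == pytest.approx(2 * tauc_from_relaxation(rec2))
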