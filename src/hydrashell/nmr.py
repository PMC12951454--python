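"""NMR-side stability observables.

Four residue-level quantities that report on hydrogen bonding and
hydration without any structure calculation:

* amide temperature coefficients (slope of the NH chemical shift vs
  temperature, in ppb/K) with the empirical hydrogen-bond rule that a
  coefficient above a threshold (-5.0 ppb/K for ubiquitin-like systems,
  -2.72 ppb/K for GB3-calibrated work) indicates an intramolecular HB;
* Pearson (optionally Spearman) correlation of two temperature-coefficient
  profiles over their matched residues;
* hydrogen-deuterium exchange protection: the intensity ratio
  I(t)/I(0) of amide cross-peaks after exchange into D2O, with residues
  counted as protected at a threshold;
* the rotational correlation time tau_c from the single-field isotropic
  R2/R1 estimator, tau_c = sqrt(6*R2/R1 - 7) / (4*pi*nu_N).

tau_c here is the closed-form approximation, not a full spectral-density
fit; it is exact for isotropic tumbling in the slow-motion limit and is
what the R2/R1 ratio alone can support.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import ObservableTable

__all__ = [
    "TempCoefficient",
    "HDXResult",
    "RelaxationRecord",
    "N15_GYROMAGNETIC_RATIO",
    "temp_coefficient",
    "classify_hbond_from_tempco",
    "tempco_correlation",
    "hdx_protection",
    "tauc_from_relaxation",
]

#: |gamma(15N)| / gamma(1H): converts a 1H spectrometer frequency to the 15N one.
N15_GYROMAGNETIC_RATIO = 0.10136767


@dataclass(frozen=True)
class TempCoefficient:
    residue: int
    slope: float  # ppb/K
    intercept: float  # ppm
    r_squared: float
    n_points: int
    hb_classified: bool


@dataclass(frozen=True)
class HDXResult:
    residue: int
    ratio: float  # I(t)/I(0)
    protected_at: dict = field(default_factory=dict)  # threshold -> bool


@dataclass(frozen=True)
class RelaxationRecord:
    residue: int
    r1: float  # 1/s
    r2: float  # 1/s
    hetnoe: float
    field_1H: float  # MHz

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("relaxation rates must be positive")


def temp_coefficient(
    table: ObservableTable,
    threshold: float = -5.0,
) -> list[TempCoefficient]:
    """Per-residue OLS slope of shift (ppm) vs temperature (K), in ppb/K.

    Residues with fewer than three points are skipped with a warning; a
    constant-shift series gets slope 0 with r^2 = 1 (a perfect flat fit).
    """
    if table.kind != "tempseries":
        raise ValueError("temp_coefficient expects a tempseries table")
    out: list[TempCoefficient] = []
    for residue, grp in table.data.dropna(subset=["temperature_K", "shift_ppm"]).groupby("residue"):
        if len(grp) < 3:
            warnings.warn(f"residue {residue}: fewer than 3 points, skipped")
            continue
        t = grp["temperature_K"].to_numpy(dtype=float)
        y = grp["shift_ppm"].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            slope_ppm, intercept, r2 = 0.0, float(y[0]), 1.0
        else:
            res = stats.linregress(t, y)
            slope_ppm, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        slope_ppb = slope_ppm * 1000.0
        out.append(
            TempCoefficient(
                residue=int(residue),
                slope=float(slope_ppb),
                intercept=float(intercept),
                r_squared=float(r2),
                n_points=len(grp),
                hb_classified=classify_hbond_from_tempco(slope_ppb, threshold),
            )
        )
    if not out:
        raise ValueError("no residue had >= 3 usable points")
    return out


def classify_hbond_from_tempco(slope: float, threshold: float = -5.0) -> bool:
    """Empirical HB rule: hydrogen bonded iff slope is strictly above threshold."""
    return slope > threshold


def tempco_correlation(
    profile_a: dict[int, float],
    profile_b: dict[int, float],
    method: str = "pearson",
) -> tuple[float, int]:
    """Correlation of two residue->slope profiles over matched residues.

    Returns (r, n_matched).  Requires at least three matched residues.
    """
    keys = sorted(set(profile_a) & set(profile_b))
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} matched residues; need >= 3")
    a = np.array([profile_a[k] for k in keys])
    b = np.array([profile_b[k] for k in keys])
    if method == "pearson":
        r = stats.pearsonr(a, b).statistic
    elif method == "spearman":
        r = stats.spearmanr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), len(keys)


def hdx_protection(
    table: ObservableTable,
    t: float = 48.0,
    thresholds: list[float] | None = None,
    inclusive_thresholds: frozenset[float] | set[float] = frozenset({0.2}),
) -> tuple[list[HDXResult], dict[float, int]]:
    """Amide-intensity retention ratios I(t)/I(0) and protected counts.

    A residue is protected at threshold theta when ratio >= theta for
    thresholds declared inclusive (the canonical 0.2 "retaining >= 20%"
    rule) and ratio > theta otherwise (the ">60%" style cuts).  Residues
    with I(0) <= 0 are excluded with a warning.
    """
    if table.kind != "hdx":
        raise ValueError("hdx_protection expects an hdx table")
    thresholds = list(thresholds) if thresholds is not None else [0.2]
    inclusive = set(inclusive_thresholds)
    data = table.data.dropna(subset=["time_h", "intensity"])

    results: list[HDXResult] = []
    for residue, grp in data.groupby("residue"):
        at0 = grp[np.isclose(grp["time_h"], 0.0)]
        att = grp[np.isclose(grp["time_h"], t)]
        if at0.empty or att.empty:
            continue
        i0 = float(at0["intensity"].iloc[0])
        it = float(att["intensity"].iloc[0])
        if i0 <= 0:
            warnings.warn(f"residue {residue}: I(0) <= 0, excluded")
            continue
        ratio = it / i0
        protected = {
            th: (ratio >= th if th in inclusive else ratio > th) for th in thresholds
        }
        results.append(HDXResult(residue=int(residue), ratio=ratio, protected_at=protected))
    if not results:
        raise ValueError("no residue had usable intensities at both time points")
    counts = {th: sum(r.protected_at[th] for r in results) for th in thresholds}
    return results, counts


def tauc_from_relaxation(record: RelaxationRecord) -> float:
    """Rotational correlation time in ns from the R2/R1 ratio.

    tau_c = sqrt(6*R2/R1 - 7) / (4*pi*nu_N) with nu_N the 15N Larmor
    frequency implied by the 1H field.  Valid only when 6*R2/R1 - 7 > 0
    (i.e. R2/R1 > 7/6, the slow-tumbling regime).
    """
    radicand = 6.0 * record.r2 / record.r1 - 7.0
    if radicand <= 0:
        raise ValueError("6*R2/R1 - 7 must be positive (outside estimator domain)")
    nu_n_hz = record.field_1H * 1e6 * N15_GYROMAGNETIC_RATIO
    tau_s = math.sqrt(radicand) / (4.0 * math.pi * nu_n_hz)
    return tau_s * 1e9


def r2_over_r1_for_tauc(tau_c_ns: float, field_1h_mhz: float) -> float:
    """Invert the tau_c estimator: the R2/R1 ratio implying a given tau_c."""
    nu_n_hz = field_1h_mhz * 1e6 * N15_GYROMAGNETIC_RATIO
    x = tau_c_ns * 1e-9 * 4.0 * math.pi * nu_n_hz
    return (x**2 + 7.0) / 6.0
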