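"""End-to-end orchestration: comparative hydration studies and the demo.

``run_hydration_study`` takes two solvated trajectories (a reference and
a comparison system, e.g. a wild-type-like and an enhanced-hydration toy)
and reports, for each hydration metric, box-plot statistics of the
post-burn-in per-frame distribution plus the A-B difference of means.
Every number is traceable to the per-stage tables the library emits.

``run_synthetic_demo`` is the self-checking toy study: it generates a
wild-type-like and an enhanced-hydration system pair, synthetic NMR
tables, and a design set, runs every analysis stage, and asserts that
each stage recovers the generator's ground truth.  It writes its tables
and a replayable run manifest (config snapshot, seed, input digests,
output paths) to an output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energetics import protein_water_energy_series
from .hbonds import hbond_counts
from .hydration import shell_counts, residence_times
from .io_formats import AnalysisConfig, FrameSeries, SolvatedSystem, write_fasta, write_observable_table, write_trajectory
from .nmr import (
    RelaxationRecord,
    hdx_protection,
    r2_over_r1_for_tauc,
    tauc_from_relaxation,
    temp_coefficient,
)
from .seqcharge import UBIQUITIN_SEQUENCE, charge_profile, counterions_for_neutrality, enrichment_stats
from .synthetic import (
    OccupancyPattern,
    WaterPlacementSpec,
    make_design_set,
    make_hdx_table,
    make_nmr_tempseries,
    make_toy_system,
    make_trajectory,
)

__all__ = ["PipelineError", "run_hydration_study", "run_synthetic_demo"]

STUDY_METRICS = [
    "n_primary",
    "n_secondary",
    "n_protein_water",
    "n_water_water_primary",
    "n_water_water_secondary",
    "energy_total",
]


class PipelineError(RuntimeError):
    """A stage assertion failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _box_stats(values: np.ndarray) -> dict[str, float]:
    return {
        "min": float(np.min(values)),
        "q1": float(np.percentile(values, 25)),
        "median": float(np.median(values)),
        "q3": float(np.percentile(values, 75)),
        "max": float(np.max(values)),
        "mean": float(np.mean(values)),
    }


def _metric_frames(
    system: SolvatedSystem,
    series: FrameSeries,
    config: AnalysisConfig,
) -> pd.DataFrame:
    shells = shell_counts(series, system, config)
    hbs = hbond_counts(series, system, config)
    energy, _ = protein_water_energy_series(series, system, config)
    df = shells.merge(hbs, on=["frame", "time"]).merge(
        energy[["frame", "time", "total"]].rename(columns={"total": "energy_total"}),
        on=["frame", "time"],
    )
    keep = df["time"] >= config.burn_in_time
    return df[keep] if keep.any() else df


def run_hydration_study(
    trajectory_a: tuple[SolvatedSystem, FrameSeries],
    trajectory_b: tuple[SolvatedSystem, FrameSeries],
    config: AnalysisConfig,
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Comparative hydration report for two trajectories under one config.

    Returns ``{"summary": DataFrame, "per_frame": {label: DataFrame}}``;
    the summary holds box statistics per metric per system and the
    difference of means (A minus B).
    """
    sys_a, ser_a = trajectory_a
    sys_b, ser_b = trajectory_b
    df_a = _metric_frames(sys_a, ser_a, config)
    df_b = _metric_frames(sys_b, ser_b, config)
    rows = []
    for metric in STUDY_METRICS:
        sa = _box_stats(df_a[metric].to_numpy(dtype=float))
        sb = _box_stats(df_b[metric].to_numpy(dtype=float))
        row = {"metric": metric}
        row.update({f"{labels[0]}_{k}": v for k, v in sa.items()})
        row.update({f"{labels[1]}_{k}": v for k, v in sb.items()})
        row["diff_of_means"] = sa["mean"] - sb["mean"]
        rows.append(row)
    return {
        "summary": pd.DataFrame(rows),
        "per_frame": {labels[0]: df_a, labels[1]: df_b},
    }


# ---------------------------------------------------------------------------
# synthetic demo
# ---------------------------------------------------------------------------

def _demo_system(seed: int, n_primary: int, n_hb: int, config: AnalysisConfig):
    """Toy system: n_primary shell waters, the first n_hb donating linear HBs."""
    placements = []
    for i in range(n_primary):
        if i < n_hb:
            placements.append(
                # anchor on the negatively charged (O) pseudo-atoms so the
                # donated H...acceptor contact is electrostatically attractive
                WaterPlacementSpec("primary", 2.8, hb_partner=5 + 2 * (i % 4), hb_geometry="linear")
            )
        else:
            placements.append(WaterPlacementSpec("primary", 3.1))
    placements += [WaterPlacementSpec("secondary", 6.0) for _ in range(4)]
    placements += [WaterPlacementSpec("bulk", 12.5) for _ in range(3)]
    return make_toy_system(12, placements, seed=seed, config=config), placements


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_synthetic_demo(seed: int = 0, out_dir: str | Path = "demo_out") -> dict:
    """Run the full toy study and assert every ground-truth recovery.

    Builds a wild-type-like system (6 primary waters, 3 hydrogen-bonded)
    and an enhanced-hydration system (16 primary waters, 8 hydrogen
    bonded), 40-frame trajectories holding those waters in shell, plus
    synthetic temperature-coefficient, HDX and relaxation inputs and a
    200-variant design set.  Raises :class:`PipelineError` naming the
    first failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = {name: int(rng.integers(2**31 - 1)) for name in
           ("wt", "enh", "traj_wt", "traj_enh", "nmr", "hdx", "designs")}
    config = AnalysisConfig(burn_in_time=400.0, seed=seed)
    outputs: dict[str, str] = {}

    # --- systems and trajectories -----------------------------------------
    (wt_system, _), _ = _demo_system(sub["wt"], n_primary=6, n_hb=3, config=config)
    (enh_system, _), _ = _demo_system(sub["enh"], n_primary=16, n_hb=8, config=config)
    n_frames, dt = 40, 100.0

    def _full_patterns(system, n_primary):
        return [
            OccupancyPattern(wi, ((0, n_frames - 1),)) for wi in range(n_primary)
        ]

    wt_series = make_trajectory(
        wt_system, _full_patterns(wt_system, 6), n_frames, dt, jitter_sd=0.02,
        seed=sub["traj_wt"], config=config,
    )
    enh_series = make_trajectory(
        enh_system, _full_patterns(enh_system, 16), n_frames, dt, jitter_sd=0.02,
        seed=sub["traj_enh"], config=config,
    )
    for name, system, series in (
        ("wildtype_like", wt_system, wt_series),
        ("enhanced_hydration", enh_system, enh_series),
    ):
        p = out / f"{name}.pdb"
        write_trajectory(p, system, series)
        outputs[f"{name}_trajectory"] = str(p)

    # --- hydration stage ---------------------------------------------------
    counts_wt = shell_counts(wt_series, wt_system, config)
    counts_enh = shell_counts(enh_series, enh_system, config)
    if not (counts_wt["n_primary"] == 6).all():
        raise PipelineError("hydration", "wild-type primary occupancy not held at 6")
    if not (counts_enh["n_primary"] == 16).all():
        raise PipelineError("hydration", "enhanced primary occupancy not held at 16")
    runs, _ = residence_times(wt_series, wt_system, config, "primary")
    if len(runs) != 6 or any(r.length != n_frames for r in runs):
        raise PipelineError("hydration", "residence runs do not match occupancy patterns")
    counts_wt.to_csv(out / "shell_counts_wildtype.csv", index=False)
    counts_enh.to_csv(out / "shell_counts_enhanced.csv", index=False)
    outputs["shell_counts"] = str(out / "shell_counts_wildtype.csv")

    # --- comparative study -------------------------------------------------
    report = run_hydration_study(
        (wt_system, wt_series), (enh_system, enh_series), config,
        labels=("wildtype", "enhanced"),
    )
    summary = report["summary"]
    primary_diff = float(
        summary.loc[summary["metric"] == "n_primary", "diff_of_means"].iloc[0]
    )
    if primary_diff != -10.0:
        raise PipelineError("study", f"primary-count mean difference {primary_diff} != -10")
    pw_wt = summary.loc[summary["metric"] == "n_protein_water", "wildtype_mean"].iloc[0]
    pw_enh = summary.loc[summary["metric"] == "n_protein_water", "enhanced_mean"].iloc[0]
    if not pw_enh > pw_wt:
        raise PipelineError("study", "enhanced system does not exceed wild-type in protein-water HBs")
    summary.to_csv(out / "study_summary.csv", index=False)
    outputs["study_summary"] = str(out / "study_summary.csv")

    # --- NMR stages ---------------------------------------------------------
    slopes = {1: -0.64, 2: 0.49, 3: 0.33, 4: -5.3, 5: -7.5, 6: -2.0}
    temps = list(range(281, 321, 5))
    ttable = make_nmr_tempseries(slopes, temps, noise_sd=0.0, seed=sub["nmr"])
    write_observable_table(out / "tempseries.tsv", ttable)
    coeffs = {c.residue: c.slope for c in temp_coefficient(ttable, config.tempco_threshold)}
    for r, s in slopes.items():
        if abs(coeffs[r] - s) > 1e-9:
            raise PipelineError("tempco", f"residue {r}: recovered {coeffs[r]} != {s}")

    protected = set(range(1, 31))
    htable = make_hdx_table(protected, k_fast=1.0, k_slow=0.01, times=[0.0, 48.0], seed=sub["hdx"])
    write_observable_table(out / "hdx.tsv", htable)
    results, counts = hdx_protection(htable, t=48.0, thresholds=[config.hdx_threshold])
    if counts[config.hdx_threshold] != len(protected):
        raise PipelineError("hdx", f"protected count {counts} != {len(protected)}")

    tau_true = 4.15
    ratio = r2_over_r1_for_tauc(tau_true, 850.0)
    tau_back = tauc_from_relaxation(RelaxationRecord(1, 1.0, ratio, 0.8, 850.0))
    if abs(tau_back - tau_true) > 1e-6:
        raise PipelineError("tauc", f"round trip {tau_back} != {tau_true}")

    # --- sequence stage -----------------------------------------------------
    ub = charge_profile(UBIQUITIN_SEQUENCE, config.charge_scheme, "Ub")
    if (ub.n_positive, ub.n_negative) != (11, 11):
        raise PipelineError("seqcharge", f"ubiquitin profile {ub.n_positive}/{ub.n_negative} != 11/11")
    if counterions_for_neutrality(ub) != (0, 0):
        raise PipelineError("seqcharge", "neutral sequence should need no counterions")
    designs = make_design_set(UBIQUITIN_SEQUENCE, 200, extra_pos=4, extra_neg=5, seed=sub["designs"])
    write_fasta(out / "designs.fasta", [("template", designs.template)] + designs.variants)
    stats = enrichment_stats(designs)
    gt = designs.ground_truth
    if abs(stats.mean_delta_pct_positive - gt["delta_pct_positive"]) > 1e-9:
        raise PipelineError("enrichment", "positive enrichment does not match ground truth")
    if abs(stats.mean_delta_pct_negative - gt["delta_pct_negative"]) > 1e-9:
        raise PipelineError("enrichment", "negative enrichment does not match ground truth")
    outputs["designs"] = str(out / "designs.fasta")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "tool": "hydrashell",
        "version": __version__,
        "seed": seed,
        "substream_seeds": sub,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "input_digests": {
            k: _digest(Path(v)) for k, v in outputs.items() if v.endswith(".pdb")
        },
        "outputs": outputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checks": {
            "primary_diff_of_means": primary_diff,
            "protein_water_hb_means": [float(pw_wt), float(pw_enh)],
            "hdx_protected_count": counts[config.hdx_threshold],
            "tauc_round_trip_ns": tau_back,
            "enrichment_mean_delta_pct_positive": stats.mean_delta_pct_positive,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
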