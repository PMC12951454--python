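#!/usr/bin/env python
"""Build the toy study pair: a wild-type-like and an enhanced-hydration
solvated system with 40-frame trajectories, written as multi-model PDB
plus a side-car nonbonded parameter table.

The wild-type-like system holds 6 waters in the primary shell (3 of them
donating linear hydrogen bonds to solute N/O atoms); the enhanced system
holds 16 (8 hydrogen bonded).  Later scripts read these files back, so
this also exercises the I/O round trip the analyses depend on.
"""

from pathlib import Path

import numpy as np

from hydrashell import AnalysisConfig, parameter_table, write_trajectory
from hydrashell.pipeline import _demo_system

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = AnalysisConfig(burn_in_time=400.0)
    rng = np.random.default_rng(SEED)
    from hydrashell import OccupancyPattern, make_trajectory

    for name, n_primary, n_hb in (("wildtype_like", 6, 3), ("enhanced_hydration", 16, 8)):
        (system, _), _ = _demo_system(int(rng.integers(2**31 - 1)), n_primary, n_hb, config)
        patterns = [OccupancyPattern(wi, ((0, 39),)) for wi in range(n_primary)]
        series = make_trajectory(system, patterns, n_frames=40, dt=100.0,
                                 jitter_sd=0.02, seed=int(rng.integers(2**31 - 1)),
                                 config=config)
        write_trajectory(OUT / f"{name}.pdb", system, series)
        print(f"{name}: {system.n_atoms} atoms, {system.n_waters} waters, "
              f"{series.n_frames} frames -> {OUT / (name + '.pdb')}")
        if name == "wildtype_like":
            parameter_table(system).to_csv(OUT / "parameters.csv", index=False)
            print(f"nonbonded parameters -> {OUT / 'parameters.csv'}")


if __name__ == "__main__":
    main()
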