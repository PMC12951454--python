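"""Rigid-body superposition of coordinate sets (Kabsch).

Used to check how closely a designed variant's structure tracks its
template fold: superpose matched atoms (typically C-alpha) and report
the RMSD after the optimal rotation/translation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["superpose", "superposed_rmsd"]


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares superpose ``mobile`` onto ``target``.

    Returns (transformed mobile coordinates, RMSD in the same units).
    Both arrays must be (n, 3) with matched rows.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 matched atoms")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    moved = rot.apply(mobile - mc) + tc
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return moved, rmsd


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal superposition."""
    return superpose(mobile, target)[1]
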