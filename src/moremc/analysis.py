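"""Pose evaluation and decoy post-processing.

Covers the standard docking diagnostics: ligand RMSD against the native pose
(Lrmsd, computed in the fixed receptor frame, success at <= 2 A), stochastic
near-duplicate elimination at the 0.65*sqrt(N) threshold, the three-stage
decoy ranking (drop non-touching, keep the top 5% by total energy, rank by
interface delta), per-replica temperature-occupancy statistics, and the
"energy versus rmsd" funnel table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energy import CONTACT_RADIUS
from .structure import AtomRecord, Pose

logger = logging.getLogger(__name__)

__all__ = [
    "LRMSD_SUCCESS",
    "DUPLICATE_COEFF",
    "TOP_FRACTION",
    "DecoyRecord",
    "OccupancyMatrix",
    "lrmsd",
    "pose_lrmsd",
    "ligand_is_touching",
    "make_decoy_record",
    "filter_near_duplicates",
    "rank_decoys",
    "temperature_occupancy",
    "funnel_table",
]

#: Docking success criterion: ligand RMSD at or below this (A).
LRMSD_SUCCESS = 2.0
#: Near-duplicate threshold is DUPLICATE_COEFF * sqrt(N) A over N heavy ligand atoms.
DUPLICATE_COEFF = 0.65
#: Fraction of touching decoys kept by the total-energy stage of the ranking.
TOP_FRACTION = 0.05


@dataclass
class DecoyRecord:
    """One predicted complex conformation with its evaluation metrics.

    ``pose`` may be None for records rehydrated from a table (ranking only
    needs the scalar columns).
    """

    pose: Pose | None
    tscore: float
    ifdelta: float
    lrmsd: float = float("nan")
    ligand_is_touching: bool = True


def _heavy_coords(atoms: Iterable[AtomRecord] | np.ndarray) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return atoms.reshape(-1, 3)
    return np.array([a.coords for a in atoms if not a.is_hydrogen]).reshape(-1, 3)


def lrmsd(pred_ligand, native_ligand) -> float:
    """Ligand RMSD over non-hydrogen atoms, receptor frame fixed (no superposition).

    Accepts :class:`AtomRecord` lists (hydrogens are skipped) or plain (m, 3)
    heavy-atom coordinate arrays in matching atom order.
    """
    a = _heavy_coords(pred_ligand)
    b = _heavy_coords(native_ligand)
    if len(a) != len(b):
        raise ValueError(f"atom count mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("no non-hydrogen atoms to compare")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pose_lrmsd(pose: Pose, native: Pose) -> float:
    """Lrmsd between two poses sharing a conformer library (atom order guaranteed)."""
    return lrmsd(pose.ligand_heavy_coords(), native.ligand_heavy_coords())


def ligand_is_touching(pose: Pose, radius: float = CONTACT_RADIUS) -> bool:
    """True when any heavy ligand atom is within ``radius`` of a heavy receptor atom."""
    rec = pose.receptor.coords[pose.receptor.heavy_mask]
    lig = pose.ligand_heavy_coords()
    if len(rec) == 0 or len(lig) == 0:
        return False
    return bool((cdist(lig, rec) < radius).any())


def make_decoy_record(pose: Pose, model, native: Pose | None = None) -> DecoyRecord:
    """Evaluate one pose into a :class:`DecoyRecord` under a full-atom model."""
    from .energy import interface_delta

    return DecoyRecord(
        pose=pose,
        tscore=float(model.score(pose)),
        ifdelta=float(interface_delta(pose, model)),
        lrmsd=pose_lrmsd(pose, native) if native is not None else float("nan"),
        ligand_is_touching=ligand_is_touching(pose),
    )


def filter_near_duplicates(
    decoys: Sequence[DecoyRecord], rng: np.random.Generator
) -> list[DecoyRecord]:
    """Stochastic near-duplicate elimination at the 0.65*sqrt(N) A threshold.

    Decoys are visited in a seeded random order; one is dropped when its
    ligand RMSD to any already-kept decoy falls below the threshold, so the
    surviving set is pairwise separated by at least 0.65*sqrt(N) A (N = heavy
    ligand atoms, shared by all decoys).
    """
    if not decoys:
        return []
    coords = [d.pose.ligand_heavy_coords() for d in decoys]
    n_heavy = coords[0].shape[0]
    if any(c.shape != coords[0].shape for c in coords):
        raise ValueError("all decoys must share one ligand")
    threshold = DUPLICATE_COEFF * math.sqrt(n_heavy)
    order = rng.permutation(len(decoys))
    kept_idx: list[int] = []
    for i in order:
        ci = coords[i]
        dup = any(
            math.sqrt(float(np.mean(np.sum((ci - coords[j]) ** 2, axis=1)))) < threshold
            for j in kept_idx
        )
        if not dup:
            kept_idx.append(int(i))
    kept_idx.sort()  # report survivors in original order
    return [decoys[i] for i in kept_idx]


def rank_decoys(decoys: Sequence[DecoyRecord]) -> list[DecoyRecord]:
    """Three-stage ranking: touching filter, top 5% by TScore, sort by IFDelta.

    Stage 2 keeps ``max(1, floor(0.05 * m))`` of the m touching decoys (the
    minimum of one avoids returning nothing from a non-empty pool). An empty
    result after stage 1 is returned as-is with a warning.
    """
    touching = [d for d in decoys if d.ligand_is_touching]
    if not touching:
        logger.warning("no decoys touch the receptor; ranking is empty")
        return []
    keep = max(1, math.floor(TOP_FRACTION * len(touching)))
    by_energy = sorted(touching, key=lambda d: d.tscore)[:keep]
    return sorted(by_energy, key=lambda d: d.ifdelta)


@dataclass(frozen=True)
class OccupancyMatrix:
    """Per-replica rung-visit frequencies plus summary statistics.

    ``frequencies[l, r]`` is the fraction of cycles replica label ``l`` spent
    on rung ``r`` (each row sums to 1). ``mean_rung``/``var_rung`` summarise
    each replica's rung trajectory; a run whose rows flatten toward 1/numR
    with small variance mixes well in temperature space.
    """

    frequencies: np.ndarray
    mean_rung: np.ndarray
    var_rung: np.ndarray

    @property
    def n_replicas(self) -> int:
        return self.frequencies.shape[0]


def temperature_occupancy(trajectory: np.ndarray) -> OccupancyMatrix:
    """Occupancy statistics from a (n_cycles, numR) rung-assignment trajectory."""
    traj = np.asarray(trajectory, dtype=np.int64)
    if traj.ndim != 2 or traj.size == 0:
        raise ValueError("trajectory must be a non-empty (n_cycles, numR) array")
    n_cycles, num_r = traj.shape
    n_rungs = max(int(traj.max()) + 1, num_r)
    freqs = np.zeros((num_r, n_rungs))
    for label in range(num_r):
        counts = np.bincount(traj[:, label], minlength=n_rungs)
        freqs[label] = counts / n_cycles
    return OccupancyMatrix(
        frequencies=freqs,
        mean_rung=traj.mean(axis=0),
        var_rung=traj.var(axis=0),
    )


def funnel_table(decoys: Sequence[DecoyRecord]) -> pd.DataFrame:
    """One row per decoy: (lrmsd, ifdelta, tscore, success) for funnel plotting."""
    return pd.DataFrame(
        {
            "lrmsd": [d.lrmsd for d in decoys],
            "ifdelta": [d.ifdelta for d in decoys],
            "tscore": [d.tscore for d in decoys],
            "success": [d.lrmsd <= LRMSD_SUCCESS for d in decoys],
        }
    )
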